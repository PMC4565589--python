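[scheme]
name = BTCS
kind = implicit

[variables]
diffvar = v
arithvar = y
constvar = z
dimensions = t x y2 z2
indices = n j k l
deltas = dt dx dy2 dz2

[replace]
y = y[n, j, k, l]
v = v[n, j, k, l]

[operators]
d(v)/d(t) = (v[n+1, j] - v[n, j]) / dt
d2(v)/d(x)2 = (v[n+1, j+1] - 2 * v[n+1, j] + v[n+1, j-1]) / dx^2
d2(v)/d(y2)2 = (v[n+1, k+1] - 2 * v[n+1, k] + v[n+1, k-1]) / dy2^2
d2(v)/d(z2)2 = (v[n+1, l+1] - 2 * v[n+1, l] + v[n+1, l-1]) / dz2^2

[boundary]
4 = x - dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
5 = x - neumann : d(v, -)/d(x) = bval => (v[n+1, j-1, k, l] - v[n+1, j, k, l]) / dx = bval @ n+1 material
6 = x + dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
7 = x + neumann : d(v, +)/d(x) = bval => (v[n+1, j, k, l] - v[n+1, j+1, k, l]) / dx = bval @ n+1 material
8 = y2 - dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
9 = y2 - neumann : d(v, -)/d(y2) = bval => (v[n+1, j, k-1, l] - v[n+1, j, k, l]) / dy2 = bval @ n+1 material
10 = y2 + dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
11 = y2 + neumann : d(v, +)/d(y2) = bval => (v[n+1, j, k, l] - v[n+1, j, k+1, l]) / dy2 = bval @ n+1 material
12 = z2 - dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
13 = z2 - neumann : d(v, -)/d(z2) = bval => (v[n+1, j, k, l-1] - v[n+1, j, k, l]) / dz2 = bval @ n+1 material
14 = z2 + dirichlet : v = bval => v[n+1, j, k, l] = bval @ n+1 material
15 = z2 + neumann : d(v, +)/d(z2) = bval => (v[n+1, j, k, l] - v[n+1, j, k, l+1]) / dz2 = bval @ n+1 material
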