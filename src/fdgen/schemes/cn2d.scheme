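[scheme]
name = CN
kind = implicit

[variables]
diffvar = v
arithvar = y
constvar = z
dimensions = t x y2
indices = n j k
deltas = dt dx dy2

[replace]
y = y[n, j, k]
v = v[n, j, k]

[operators]
d(v)/d(t) = (v[n+1, j] - v[n, j]) / dt
d2(v)/d(x)2 = (v[n, j+1] - 2 * v[n, j] + v[n, j-1]) / (2 * dx^2) + (v[n+1, j+1] - 2 * v[n+1, j] + v[n+1, j-1]) / (2 * dx^2)
d2(v)/d(y2)2 = (v[n, k+1] - 2 * v[n, k] + v[n, k-1]) / (2 * dy2^2) + (v[n+1, k+1] - 2 * v[n+1, k] + v[n+1, k-1]) / (2 * dy2^2)

[boundary]
4 = x - dirichlet : v = bval => v[n, j, k] = bval @ n material | v[n+1, j, k] = bval @ n+1 material
5 = x - neumann : d(v, -)/d(x) = bval => (v[n, j-1, k] - v[n, j, k]) / dx = bval @ n material | (v[n+1, j-1, k] - v[n+1, j, k]) / dx = bval @ n+1 material
6 = x + dirichlet : v = bval => v[n, j, k] = bval @ n material | v[n+1, j, k] = bval @ n+1 material
7 = x + neumann : d(v, +)/d(x) = bval => (v[n, j, k] - v[n, j+1, k]) / dx = bval @ n material | (v[n+1, j, k] - v[n+1, j+1, k]) / dx = bval @ n+1 material
8 = y2 - dirichlet : v = bval => v[n, j, k] = bval @ n material | v[n+1, j, k] = bval @ n+1 material
9 = y2 - neumann : d(v, -)/d(y2) = bval => (v[n, j, k-1] - v[n, j, k]) / dy2 = bval @ n material | (v[n+1, j, k-1] - v[n+1, j, k]) / dy2 = bval @ n+1 material
10 = y2 + dirichlet : v = bval => v[n, j, k] = bval @ n material | v[n+1, j, k] = bval @ n+1 material
11 = y2 + neumann : d(v, +)/d(y2) = bval => (v[n, j, k] - v[n, j, k+1]) / dy2 = bval @ n material | (v[n+1, j, k] - v[n+1, j, k+1]) / dy2 = bval @ n+1 material
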