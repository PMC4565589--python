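[scheme]
name = BTCS
kind = implicit

[variables]
diffvar = v
arithvar = y
constvar = z
dimensions = t x
indices = n j
deltas = dt dx

[replace]
y = y[n, j]
v = v[n, j]

[operators]
d(v)/d(t) = (v[n+1, j] - v[n, j]) / dt
d2(v)/d(x)2 = (v[n+1, j+1] - 2 * v[n+1, j] + v[n+1, j-1]) / dx^2

[boundary]
4 = x - dirichlet : v = bval => v[n+1, j] = bval @ n+1 material
5 = x - neumann : d(v, -)/d(x) = bval => (v[n+1, j-1] - v[n+1, j]) / dx = bval @ n+1 material
6 = x + dirichlet : v = bval => v[n+1, j] = bval @ n+1 material
7 = x + neumann : d(v, +)/d(x) = bval => (v[n+1, j] - v[n+1, j+1]) / dx = bval @ n+1 material
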