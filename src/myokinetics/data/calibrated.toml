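[protocol]
epsilon = 0.1
t_strain = 3.0
t_end = 21.0

[initial]
n0 = 90000.0
n1 = 0.0
n2 = 0.0
n3 = 0.0
n4 = 0.0

[feedback]
n_dagger = 325000.0
s = 3.5e-05

[switches]
n1_star = 67500.0
n3_star = 126000.0
n1_dstar = 72562.5
n3_dstar = 138600.0
n1_release = 30375.0
suppression_enabled = true

[solver]
method = "RK45"
rtol = 1e-08
atol = 1e-06
dense_dt = 0.05
max_step = 0.25
blend_width = 0.25
rk4_dt = 0.001
onset_tol = 1.0

[rates.static.medium]
r = [0.8, 0.9, 1.0, 1.0, 0.0]
p = [0.4, 0.6, 0.2, 0.0, 0.0]
d = [0.2, 0.2, 0.2, 0.0, 0.0]
D = 0.0

[rates.static.pre_peak]
r = [0.8, 0.9, 1.0, 1.0, 0.0]
p = [0.4, 0.6, 0.2, 0.0, 0.0]
d = [0.2, 0.2, 0.2, 0.0, 0.0]
D = 0.0

[rates.static.decline]
r = [0.8, 0.0, 1.0, 1.0, 0.0]
p = [0.4, 0.1, 0.2, 0.0, 0.0]
d = [0.2, 0.6, 0.2, 0.0, 0.0]
D = 0.0

[rates.static.post_myod]
r = [0.8, 0.0, 0.8, 1.0, 0.0]
p = [0.4, 0.1, 0.2, 0.1, 0.0]
d = [0.2, 0.6, 0.2, 0.25, 0.0]
D = 0.0

[rates.static.post_mhc]
r = [0.8, 0.0, 0.8, 1.0, 0.0]
p = [0.4, 0.1, 0.2, 0.1, 0.0]
d = [0.2, 0.6, 0.2, 0.25, 0.0]
D = 0.05

[rates.dynamic.medium]
r = [0.8, 0.9, 1.0, 1.0, 0.0]
p = [0.4, 0.6, 0.2, 0.0, 0.0]
d = [0.2, 0.2, 0.2, 0.0, 0.0]
D = 0.0

[rates.dynamic.pre_peak]
r = [0.6, 0.9, 1.0, 1.0, 0.0]
p = [0.1, 0.3, 0.4, 0.0, 0.0]
d = [0.2, 0.0, 0.1, 0.0, 0.0]
D = 0.0

[rates.dynamic.decline]
r = [0.6, 0.0, 1.0, 1.0, 0.0]
p = [0.1, 0.2, 0.4, 0.0, 0.0]
d = [0.2, 0.35, 0.3, 0.0, 0.0]
D = 0.0

[rates.dynamic.post_myod]
r = [0.6, 0.0, 0.5, 1.0, 0.0]
p = [0.1, 0.2, 0.4, 0.3, 0.0]
d = [0.2, 0.35, 0.1, 0.2, 0.0]
D = 0.0

[rates.dynamic.post_mhc]
r = [0.6, 0.0, 0.5, 1.0, 0.0]
p = [0.1, 0.2, 0.4, 0.3, 0.0]
d = [0.2, 0.35, 0.1, 0.2, 0.0]
D = 0.55
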