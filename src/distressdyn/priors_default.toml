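[prev0]
family = "truncated-normal"
loc = 0.1464
scale = 0.0293
low = 0.0
high = 1.0

[P0]
family = "truncated-normal"
loc = 16167328.0
scale = 3233466.0
low = 0.0

[g]
family = "truncated-normal"
loc = 308538.0
scale = 61708.0

[D0]
family = "truncated-normal"
loc = 136840.0
scale = 27368.0
low = 0.0

[h]
family = "truncated-normal"
loc = 2228.7
scale = 445.7

[gamma]
family = "shifted-lognormal"
mu = -0.7733
sigma = 0.4701
shift = 1.0

[i0]
family = "truncated-normal"
loc = 0.0
scale = 0.5
low = 0.0

[delta_i]
family = "truncated-normal"
loc = 0.0
scale = 0.5

[s]
family = "shifted-lognormal"
mu = -1.1315
sigma = 0.2024
shift = 0.0

[C0]
family = "truncated-normal"
loc = 305315.0
scale = 61063.0
low = 0.0

[u]
family = "truncated-normal"
loc = 43696.0
scale = 8739.0

[r0]
family = "truncated-normal"
loc = 0.1845
scale = 0.0369
low = 0.0
high = 1.0

[delta_r]
family = "truncated-normal"
loc = 0.0
scale = 0.0125

[beta_distress]
family = "log10-normal"
loc = 1.0
scale = 1.0

[beta_population]
family = "log10-normal"
loc = 1.0
scale = 1.0

[beta_mortality]
family = "log10-normal"
loc = 1.0
scale = 1.0

[beta_services]
family = "log10-normal"
loc = 1.0
scale = 1.0
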