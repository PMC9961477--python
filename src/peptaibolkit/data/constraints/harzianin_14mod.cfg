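# Substrate predictions for the 14-module hybrid PKS-NRPS (BGC 8.3 type,
# harzianin-like). Pro modules 5, 9, 13 form a single monophyletic clade;
# Aib is inferred for modules 1, 4, 8, 12; modules 3, 7, 10, 11 are
# promiscuous for Lxx/Vxx. Skipping is enabled: this synthetase also yields
# 11-residue peptaibols by omitting a run of modules.

[synthetase]
name = harzianin_14mod
allow_skipping = true
max_skipped_run = 3

[module 1]
allowed = Aib
hard = false

[module 2]
allowed = Gly, Gln, Glu
hard = false

[module 3]
allowed = Lxx, Vxx
hard = false

[module 4]
allowed = Aib
hard = false

[module 5]
allowed = Pro
hard = true
note = Pro clade, monophyletic

[module 6]
allowed = Ala
hard = false

[module 7]
allowed = Lxx, Vxx
hard = false

[module 8]
allowed = Aib
hard = false

[module 9]
allowed = Pro
hard = true
note = Pro clade, monophyletic

[module 10]
allowed = Lxx, Vxx
hard = false

[module 11]
allowed = Lxx, Vxx
hard = false

[module 12]
allowed = Aib
hard = false

[module 13]
allowed = Pro
hard = true
note = Pro clade, monophyletic

[module 14]
allowed = Lxxol, Pheol, Vxxol
hard = false
note = C-terminal amino-alcohol module
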