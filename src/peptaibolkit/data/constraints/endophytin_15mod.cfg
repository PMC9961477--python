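# Substrate predictions for the 15-module peptaibol synthetase (BGC 19.1 type).
# Derived from adenylation-domain phylogeny; only modules 1 and 2 are binding
# (hard), reflecting their unambiguous clade placement (100% and >92%
# bootstrap). Promiscuous or weakly supported modules are soft: violations
# demote a candidate but do not eliminate it. Module 10 encodes both the
# phylogenetic prediction (Ser) and the residue actually observed across all
# endophytins (Ala).

[synthetase]
name = endophytin_15mod
allow_skipping = false
max_skipped_run = 0

[module 1]
allowed = Aib
hard = true
note = Aib clade, 100% bootstrap

[module 2]
allowed = Ala
hard = true
note = Ala-specific, >92% bootstrap, non-promiscuous

[module 3]
allowed = Aib, Ala, Vxx, Lxx
hard = false
note = predicted for varied amino acids

[module 4]
allowed = Ala
hard = false

[module 5]
allowed = Aib
hard = false

[module 6]
allowed = Gly, Gln, Glu
hard = false

[module 7]
allowed = Aib, Ala, Vxx, Lxx
hard = false
note = predicted for varied amino acids

[module 8]
allowed = Aib, Ala, Lxx, Vxx
hard = false
note = clades with affinity for Aib/Lxx/Vxx/Ala

[module 9]
allowed = Aib
hard = false

[module 10]
allowed = Ser, Ala
hard = false
note = phylogeny predicts Ser; observed residue is Ala

[module 11]
allowed = Aib
hard = false

[module 12]
allowed = Aib
hard = false

[module 13]
allowed = Aib, Ala
hard = false

[module 14]
allowed = Gly, Gln, Glu
hard = false

[module 15]
allowed = Lxxol, Pheol, Vxxol
hard = false
note = C-terminal amino-alcohol module
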