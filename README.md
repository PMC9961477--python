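# peptaibolkit

Annotation tooling for **peptaibols** — linear fungal nonribosomal peptides
with an acetylated N-terminus, a C-terminal amino alcohol, and a backbone
rich in α-aminoisobutyric acid (Aib). Peptaibols are invisible to standard
proteomics software: their residues are noncanonical, their precursors are
singly charged [M+H]⁺ ions, and their CID spectra are dominated by a b-ion
acylium ladder rather than the usual b/y mixture. `peptaibolkit` implements
the desk workflow a natural-products group uses to sequence them:

1. **Exact-mass chemistry** for the noncanonical alphabet
   (Gly, Ala, Aib, Ser, Pro, Vxx = Val/Iva, Lxx = Leu/Ile, Gln, Glu;
   amino alcohols Lxxol, Pheol, Vxxol), with monoisotopic and nominal
   (integer) mass arithmetic and Hill-order formula handling.
2. **b-ion ladder de novo sequencing.** The amino-alcohol neutral loss from
   [M+H]⁺ (−117.1154 for leucinol/isoleucinol, −151.0997 for phenylalaninol)
   anchors the b(n−1) ion; successive peak differences are residue masses
   (b_i − b_{i−1} = m(residue i)); the unobservable b1/b2 region is completed
   combinatorially from the residual N-terminal mass
   (m(b_k) − m(acetyl) − m(H)).
3. **NRPS module collinearity.** Peptaibol synthetases are assembly lines:
   module order dictates residue order, and adenylation-domain phylogeny
   predicts per-module substrate sets. Encoded as hard/soft constraint
   configs, these resolve orderings the fragments cannot (e.g. an
   Aib/Ala/Aib N-terminal prefix), and module *skipping* aligns peptides
   shorter than the module count.
4. **Molecular networking.** GNPS-style modified cosine
   (√-intensity, L2-normalized, greedy one-to-one matching of direct and
   precursor-shifted peak pairs), thresholded edges (cosine ≥ 0.65,
   ≥ 4 matched peaks), connected components, and annotation of edge mass
   deltas against residue-substitution arithmetic (e.g. Δ 14.0157 = CH₂ =
   Ala↔Aib or Vxx↔Lxx; Δ 0.9840 = Gln↔Glu).

A seeded synthetic-spectrum generator (b3..b(n−1) ladder, precursor family,
ppm-scale jitter, peak dropout, noise peaks) and a packaged table of the 21
endophytins — 15-residue peptaibols of the template
`Ac-Aib-Ala-Aib-Ala-AA1-Gln-AA2-AA3-Aib-Ala-Aib-Aib-AA4-AA5-AA6ol` — make
every stage testable without instrument data.

## Worked example

Check a molecular formula against a measured precursor:

```console
$ peptaibolkit mass C63H111N17O18 --observed 1394.8370
input               C63H111N17O18  (formula)
composition         C63H111N17O18
monoisotopic mass   1393.8293
nominal mass        1393
[M+H]+ m/z          1394.8371
ppm vs observed     -0.09
```

The neutral monoisotopic mass is 1393.8293 Da; protonation (hydrogen-atom
convention, +1.0078250) gives a theoretical [M+H]⁺ of 1394.8371, −0.09 ppm
from the measured value — well inside QTOF accuracy.

Simulate a spectrum of endophytin A2 and sequence it back:

```console
$ peptaibolkit simulate --name A2 --out a2.mgf
wrote 1 spectra to a2.mgf
$ peptaibolkit denovo --mgf a2.mgf --constraints endophytin_15mod
  spectrum_id  experimental_mz  theoretical_mz  ppm       formula \
Endophytin A2        1394.8371       1394.8371 -0.0 C63H111N17O18 \
                                                        sequence  score prefix_resolved_by
Ac-Aib-Ala-Aib-Ala-Aib-Gln-Aib-Vxx-Aib-Ala-Aib-Aib-Ala-Gln-Lxxol 0.9231  module_constraint
```

The ladder fixes residues 4–14 and the C-terminal leucinol/isoleucinol; the
b3 mass (284.1610) admits two Aib and one Ala (plus isobaric alternatives),
and the hard module-2 constraint (Ala, >92% bootstrap support) collapses the
orderings to Aib-Ala-Aib — `prefix_resolved_by = module_constraint`. The
score is ladder coverage (12 of 13 possible b ions; b2 is never observed)
damped by mass error.

Other entry points: `peptaibolkit fragment` (theoretical ion tables),
`peptaibolkit network` (molecular networks + GraphML/TSV export),
`peptaibolkit annotate` (full pipeline, one TSV record per spectrum),
`peptaibolkit constraints show|validate` (module-constraint configs).
Everything is also available as a library (`import peptaibolkit`).

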