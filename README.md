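# pepsense

Antisense (complementary) peptide design and binding-affinity toolkit.

Antisense peptide technology exploits a property of the genetic code: the
peptide encoded by the complementary mRNA strand of a sense peptide tends to
carry residues of opposite polarity, position for position, and sense–
antisense peptide pairs bind each other with elevated probability (the
"Proteomic Code" idea). `pepsense` turns that idea into a reproducible
three-step pipeline for people designing peptide ligands, immunochemical
reagents or lead compounds against a chosen protein epitope:

1. **Find the epitope** (`pepsense.epitope_scan`) — sliding-window
   Hopp–Woods hydrophilicity profiles and the EIIP/Resonant Recognition
   periodogram `I(k/N) = (a_k² + b_k²)·N/2` locate candidate interaction
   hot spots on a protein sequence.
2. **Design the paratope** (`pepsense.genetic_code`,
   `pepsense.paratope_design`) — the sense→antisense residue map is derived
   from the standard codon table (complement U↔A, C↔G; read in place for
   3'→5', reversed for 5'→3'; stops dropped), the epitope becomes a
   degenerate pattern of residue sets, pentapeptide windows are enumerated
   as concrete candidates, exported to FASTA for an external blastp screen
   against antibody sequences, re-ranked by distinct hits, and selected
   motifs are joined into the final antisense peptide.
3. **Measure the affinity** (`pepsense.binding_models`) — a 1:1 equilibrium
   `K_d = [A][L]/[AL]` with the exact quadratic solution for `[AL]` is fit
   by nonlinear least squares (in log10 K_d, multi-start) to fluorescence
   titrations or thermophoresis dose–response curves; SVD species counting,
   bootstrap confidence intervals and a seeded titration simulator round
   out the module.

The worked example throughout is the C-terminal receptor-binding epitope of
human erythropoietin (EPO-P2, `LKLYTGEACRTGDR`) and its designed antisense
peptide `DFDIWPLRTAWPLS`.

## Worked example

Design the antisense pattern of the EPO-P2 epitope:

```
$ pepsense design --epitope LKLYTGEACRTGDR
# epitope = LKLYTGEACRTGDR
# direction = 3to5
# pattern = αFαεδPLRTζδPLζ
# cardinality = 288
# offset	start_1based	motif	cardinality
0	1	αFαεδ	36
1	2	FαεδP	12
2	3	αεδPL	12
3	4	εδPLR	4
4	5	δPLRT	2
5	6	PLRTζ	2
6	7	LRTζδ	4
7	8	RTζδP	4
8	9	TζδPL	4
9	10	ζδPLζ	8
```

Each epitope position maps to its antisense residue set (α = {D,E,N},
δ = {W,C}, ε = {M,I}, ζ = {A,S}; single letters are singleton sets); the
full pattern represents 288 concrete antisense peptides, and each
pentapeptide window's cardinality is the product of its set sizes. The
window at offset 0 (`αFαεδ`, 36 candidates) contains `DFDIW`; joining
`DFDIW + PLRTA + WPLS` yields `DFDIWPLRTAWPLS`.

Simulate a titration of 2.5 µM antisense peptide (titrant 1.2–75 µM, true
K_d = 850 µM) and refit it:

```
$ pepsense simulate --kd 850 --noise-sd 0.0 --out titr.csv
$ pepsense fit titr.csv
mode: fluorescence
n_points: 12
Kd_uM: 850
Kd_se_uM: 2.37128e-05
q_free: 1
q_complex: 3
rmse: 2.22996e-10
converged: True
```

The fit recovers the simulated dissociation constant (850 µM) exactly on
noiseless data; `q_free`/`q_complex` are the per-µM signal coefficients of
the free peptide and the complex, and `Kd_se_uM` is the asymptotic standard
error (essentially zero without noise).

The same functions are importable directly:

```python
import numpy as np
import pepsense as ps

amap = ps.build_antisense_map(ps.Direction.THREE_TO_FIVE)
ps.pair_count(amap)                      # 27 sense–antisense pairs
amap["L"]                                # frozenset({'D', 'E', 'N'})

truth = ps.BindingParams(kd=850.0, q_free=1.0, q_complex=3.0)
series = ps.simulate_titration(truth, 2.5, np.geomspace(1.2, 75, 12))
ps.fit_fluorescence(series).params.kd    # 850.0
```

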