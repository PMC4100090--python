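# Methods

`pepsense` implements a three-step workflow for designing an antisense
(complementary) peptide against a chosen protein epitope and estimating its
binding affinity. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data machinery
does and does not demonstrate.

## 1. Epitope hot-spot detection (`epitope_scan`)

Two independent per-residue encodings are provided, both packaged as exact
20-entry tables:

* **Hopp–Woods hydrophilicity** (kcal/mol-derived solvent parameters). The
  windowed arithmetic mean over a sliding window marks hydrophilic,
  surface-exposed stretches, the classic predictor of antigenic regions.
  Window default **6 aa**, the traditional Hopp–Woods choice for short
  antigenic determinants; values are reported at 1-based window centers
  (offset ⌈w/2⌉) and the profile carries no end padding, so it is
  `len(seq) − w + 1` points long — the ends carry no full-window
  information and inventing values there would only smooth away real peaks.
* **EIIP / Resonant Recognition Method.** Each residue is replaced by its
  electron–ion interaction pseudo-potential (Rydberg units) and the
  periodogram of the series is computed at the Fourier frequencies
  `k/N, k = 1..⌊N/2⌋`:

      I(k/N) = (a_k² + b_k²) · N/2,   a_k = (2/N) Σ x_t cos(2πkt/N),
                                      b_k = (2/N) Σ x_t sin(2πkt/N),

  evaluated via the FFT as `(2/N)|X_k|²`. Mean-centering defaults **on**
  (RRM convention); it only affects the unreported k = 0 term, so the flag
  is exposed for transparency rather than effect. Peaks are strict local
  maxima (greater than both neighbours, no smoothing), ranked by power with
  ties broken toward the lower frequency; `k = 5` peaks by default. The
  sequence-position estimate of a peak is `2 · frequency · N`; the formula
  is applied verbatim, and mapping peaks to residue regions is left to the
  user — the RRM literature gives no sharper operational rule.

Scale comparisons use the **Pearson** product-moment correlation (two-sided
p from the t distribution, 18 df for the 20-residue scale comparison).
Pearson was fixed because the compared quantities are interval-scaled
physical values; across the 20 amino acids the two packaged scales correlate
at r = 0.162 (p ≈ 0.49), i.e. they carry close to independent information.

## 2. Antisense mapping and paratope design (`genetic_code`, `paratope_design`)

The sense→antisense amino-acid relation is **derived at run time** from the
standard genetic code (translation table 1, via Biopython), never stored:
for each amino acid, every codon is complemented base-wise (U↔A, C↔G);
for the 3'→5' direction the complemented triplet is read in place, for the
5'→3' direction it is read backwards (reverse complement); antisense
triples that are stop codons are silently discarded (no published antisense
table contains stop entries); the translated residues are unioned. This
convention — in-place vs. reversed — is the one that reproduces the
published 27 (3'→5') and 52 (5'→3') pair counts and the full published
table cell-for-cell; both derived maps are symmetric relations because
complementation and reverse-complementation are involutions on codons.
Greek group labels (α = {D,E,N}, δ = {W,C}, ε = {M,I}, ζ = {A,S}, …) are
attached as display metadata keyed by the *sense* residue, because in the
5'→3' map two different sense residues (R, G) share the same antisense set
under different labels. Alternative genetic codes and codon-usage
weighting are out of scope.

An epitope maps position-wise to a **degenerate pattern** (one antisense
residue set per epitope position; position order preserved — any reversal
is inside the per-codon mapping). Its Cartesian product, enumerated in
lexicographic order with alphabetically sorted position sets, is the
candidate paratope library; the count is the product of set sizes. Windows
default to pentapeptides. Candidates are exported as FASTA with IDs
encoding `(window offset, enumeration index)` so that an external
protein–protein BLAST screen against antibody sequences can be re-imported
(12-column tabular) and windows re-ranked by **distinct subjects hit**
(ties toward the leftmost offset). The library never invokes BLAST itself;
tests and fixtures use packaged mock hit files.

For the worked example — the C-terminal receptor-binding epitope of human
erythropoietin, `LKLYTGEACRTGDR` — the 3'→5' pattern is
`αFαεδPLRTζδPLζ` (288 peptides), and joining the motif choices
`DFDIW + PLRTA + WPLS` reproduces the designed antisense peptide
`DFDIWPLRTAWPLS`, which validates position-wise against the epitope. Note
two quirks of the published motif table this package deliberately does not
reproduce: its header prints a 15-residue epitope variant whose first motif
is consistent with neither sequence (we adopt the 14-residue epitope printed
everywhere else, so our windows at offsets 0–9 correspond to published
motifs 2–11), and the printed count for the `PLRTζ` motif (4) contradicts
the product rule (1·1·1·1·2 = 2); the package returns 2.

## 3. Binding model and K_d estimation (`binding_models`)

A single 1:1 equilibrium, `Kd = [A][L]/[AL]`, with the exact quadratic
solution evaluated in the cancellation-free form
`[AL] = 2·A_t·L_t / (b + √(b² − 4·A_t·L_t))`, `b = A_t + L_t + Kd`; mass
balance holds to machine precision and [AL] is monotone in the titrant
total and antitone in Kd. Two observation models:

* fluorescence titration: `signal = baseline + q_free·[A] + q_complex·[AL]`
  (exactly two spectrally active species — the titrant is dark);
* thermophoresis dose–response: `R = R_un + (R_b − R_un)·[AL]/A_t`.

Fitting is unweighted nonlinear least squares, parameterised in
**log10 Kd** (bounded to ±9, i.e. fM–M in µM units, purely to keep the
exponential finite during line searches), with convergence tolerances
1e-12 and a **7-point multi-start** over log-spaced Kd initial values
spanning `[0.1·min titrant, 100·max titrant]` whenever no initial guess is
given. The reported `Kd_se` is the delta-method transform of the log10 Kd
standard error from the covariance at the optimum. The **baseline is held
fixed** (default 0, settable through the initial-guess object): with a
fixed fluorophore total, baseline and `q_free` enter the model only through
`baseline + q_free·A_t` plus a term in [AL], so freeing both would make the
normal equations singular. A residual-resampling bootstrap percentile
interval is offered alongside the asymptotic SE, since published "±" values
on Kd can mean either replicate SD or fit SE; the package takes no position.

Degenerate inputs are rejected loudly: constant signal (parameters
unidentifiable), fewer than 4 points, unsorted or non-positive titrant
grids.

**Species counting.** Before committing to the two-species model, the
number of spectrally active species in a titration spectra matrix is
estimated by SVD: singular values are compared to the largest value
expected from a pure-noise matrix of the stated per-element noise SD,
`σ(√m + √n)` (the Marchenko–Pastur edge), inflated by a default margin of
1.1 because the noise edge fluctuates upward (Tracy–Widom) with probability
≈ 1/2; without the margin the "pure noise → 0 species" behaviour would be
a coin flip.

## 4. Synthetic data: what it emulates and what it does not

The published titration figures do not print their raw points, so the
simulator is the test substrate and the published Kd values (850 ± 160 µM
by fluorescence, 816 ± 32 µM by thermophoresis) serve as realistic
*regimes*, not as fit targets. `simulate_titration` reproduces the
published designs — 2.5 µM fixed antisense peptide with 12 titrant levels
spanning 1.2–75 µM (fluorescence; 25 °C, pH 7.4 recorded as metadata), and
10 µM fixed with a serial dilution of the titrant (thermophoresis) — with
Gaussian noise, either absolute or multiplicative (a fraction of the clean
signal at each point), seeded mandatorily on every stochastic path. Signal
coefficients default to `q_free = 1, q_complex = 3` in arbitrary
fluorescence-ratio units: a ~3-fold intensity change of a tryptophan-bearing
peptide upon complexation is at the generous end of realistic.

What passing tests show: the estimator recovers known parameters from data
generated by its own forward model — noiseless fits are exact to optimizer
tolerance across Kd from 10 µM to 5 mM on the published design, and under
2% multiplicative noise the recovered Kd is median-unbiased to < 0.05
log10 units when the true Kd sits inside the titrant window (the
Monte-Carlo runs at Kd = 10 µM, the geometric mean of the 1.2–75 µM grid).
What they do not show: robustness to real-data pathologies (inner-filter
effects, photobleaching, pipetting error in the titrant grid, heteroscedastic
instrument noise), and — worth stating plainly — a Fisher-information
analysis of the published fluorescence design shows that with a maximum
titrant of 75 µM a true Kd near 850 µM (~8% saturation) is only weakly
identified: the CRLB on ln Kd exceeds 0.8 at 2% noise however the noise is
referenced. Precise Kd values in that regime require either replicate
titrations (the published fluorescence value is a mean ± SD across
titrations) or a titrant range extending toward Kd, as the thermophoresis
design's 10 mM stock allows.

## 5. Known limitations

* Single-wavelength isotherm fitting only; full multi-wavelength factor
  analysis (SPECFIT-style global refinement) is reduced to SVD species
  counting.
* No cooperative or multi-site models; no ITC/SPR; no CD interpretation.
* The RRM peak→region mapping is the verbatim `2·f·N` estimate; consensus
  spectra over protein families are not implemented.
* Homology screening is plumbing only (FASTA out, tabular in); no database
  ships with the package.
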