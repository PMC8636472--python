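# Methods

This note documents the models, conventions and numerical choices behind
`quadstruct`, in the spirit of a package's own methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## CD spectral decomposition

A measured spectrum is modelled as a linear combination of two reference
component spectra, the antiparallel (GQ-AP) and parallel (GQ-P) folds:

    S(λ) = x·AP(λ) + y·P(λ),   x + y = 1.

Substituting y = 1 − x makes the constrained least-squares problem
one-dimensional with the closed form

    x* = Σλ (S − P)(AP − P) / Σλ (AP − P)².

Choices and caveats:

- **Non-negativity is not imposed by default.** Only the sum constraint is
  part of the model; x outside [0, 1] is physically meaningless but
  diagnostically useful (it flags a spectrum outside the basis span).
  `clip=True` truncates to [0, 1] and sets a `clipped` flag with a warning.
- **Grids.** Spectra must sit on a uniform ascending wavelength grid;
  mismatched spectra are linearly interpolated onto the basis grid, and
  extrapolation is an error rather than a guess. Default synthetic grid:
  220–320 nm, 1 nm step (instrument scan ranges for GQ work conventionally
  span this window).
- **Degenerate basis.** AP ≡ P makes the problem ill-posed and raises
  immediately.
- **Units** are arbitrary but must be consistent between spectrum and
  basis; no mdeg↔Δε conversion is attempted.

Topology classification (`classify_topology`) is a deliberately coarse
rule on the three diagnostic wavelengths, using the extremal value within
±3 nm of 295/260/240 nm and a threshold τ = 10 % of the spectrum's absolute
maximum: AP requires S(295) > τ and S(295) > S(260); P requires
S(260) > τ and S(240) < −τ/4; both → `mixed`, neither → `non-GQ`.
Quantitative population statements should come from the decomposition
(x ≥ 0.7 AP-dominant, x ≤ 0.3 P-dominant), not the classifier.

Smoothing is Savitzky–Golay with 4 neighbours each side and a 2nd-order
polynomial by default — the common spectroscopy setting; a degree-2 filter
reproduces quadratics exactly, which the tests use as the filter oracle.

## Melt-curve fitting

Unfolding at 295 nm is modelled as a two-state transition with the
four-parameter Boltzmann sigmoid

    S(T) = lo + (up − lo) / (1 + exp((T − Tm)/w)),   w > 0,

where Tm is the plateau midpoint. The generic label "sigmoidal fit" does
not pin down a functional form; the Boltzmann form is the standard choice
for optical melts and is what the package commits to. The transition
direction (decaying folded band vs rising signal) is auto-detected from the
end-to-end signal change and absorbed into the plateau roles so w stays
positive.

- **Initialization**: plateaus from the 10th/90th signal percentiles, Tm at
  the steepest finite-difference slope, w = span/10. Fitting is
  `scipy.optimize.curve_fit` with Tm bounded to [Tmin − 10, Tmax + 10] °C.
- **Convergence flag**: the fit is marked unconverged when the optimizer
  fails, the curve is flat (range ≤ 1e−8 of its scale), the fitted
  amplitude is negligible, the Tm standard error exceeds the temperature
  span, or Tm lands at/outside the observed range — the last matters
  because a quadruplex melting near the top of a 25–90 °C scan leaves the
  upper plateau weakly constrained, and the flag exposes that rather than
  silently extrapolating.
- **Tm comparison**: unpaired two-tailed Student t-test with pooled
  (equal) variance by default — the minimal reading of "unpaired,
  two-tailed"; Welch is available via `equal_var=False`. Two zero-variance
  identical groups return p = 1 by convention.

## Sequences

0-based coordinates throughout; a CpG site is the index of its C. Only the
given strand is scanned for CpG context — the methylated oligo in the
motivating experiments is the G-rich coding strand itself, and
reverse-complement scanning is out of scope. Methylation state is a
per-position flag (IUPAC has no 5mC letter); serialization is FASTA plus a
JSON sidecar of methylated positions. A brute-force dinucleotide scan is
the test oracle. One verified arithmetic fact worth recording: each
CC|GG junction of the repeat contributes one CpG, so `(G4C2)n` + `GGGG`
has n sites while the bare `(G4C2)n` has n − 1.

## Structure model and editing

Atomic models are flat atom tables (pandas) with PDB interchange through
Biopython. Residue names follow the PDB chemical component dictionary
(DA/DC/DG/DT, 5CM for 5-methyl-dC, BGM for 8-bromo-dG, K for potassium)
for viewer interoperability.

- **Hydrogens are optional everywhere**; all geometric criteria use heavy
  atoms only (donor–acceptor distances, not H-bond angles), so heavy-atom
  deposited models work unchanged.
- **Tetrad detection**: guanine a → b when d(N1a, O6b) ≤ cutoff and
  d(N2a, N7b) ≤ cutoff (default 3.5 Å); tetrads are directed 4-cycles,
  deduplicated by residue set with ties broken by smallest total distance.
  Planes are total-least-squares fits over the 4×9 purine ring atoms. The
  stack axis is the first principal component of tetrad centroids, oriented
  so the tetrad containing the 5′-most guanine gets index 0.
- **Editing** (delete, mutate, 3′ append, strand fusion, 5mC addition)
  conserves every atom outside the edited selection bit-for-bit. Mutation
  aligns an idealized base template on the glycosidic frame (C1′, glycosidic
  N, bonded ring C); BGM→DG just drops the bromine. The 5mC methyl carbon
  (named C7, as in thymine) is placed in the base plane at 1.50 Å from C5,
  directed away from the ring centroid — the geometric reading of "a methyl
  on ring atom 5 of every cytosine preceding a guanine".
- **No minimization.** The original modelling workflow energy-minimized
  after each edit; force-field work is explicitly out of scope here.
  Instead `count_clashes` (non-bonded heavy-atom pairs under 2.0 Å,
  excluding same-residue and sequence-adjacent pairs) and junction-gap
  records tell downstream users where refinement is needed. Appended and
  fused geometry is flagged "unrefined" in metadata.
- **Strand-fusion fidelity note**: applying the documented four-strand edit
  recipe (delete T1–T2, mutate residue 7 to G, append 3′ dC, fuse) to a
  TTGGGGT tetramer yields per-strand GGGGGC — G·C-type loops rather than
  the repeat's C·C. The operations reproduce the stated steps verbatim and
  do not "fix" them; the test suite asserts the 24-residue, 3-junction
  outcome as stated.

## Idealized GQ builder

`build_ideal_gq` produces a deterministic, unrefined quadruplex for any
sequence with four equal G-tracts (length ≥ 2):

- Base templates are literal planar heavy-atom coordinates in the standard
  base reference frame; the deoxyribose/phosphate moiety is constructed
  programmatically (regular-pentagon pentose in the plane spanned by the
  glycosidic direction and base normal, standard bond lengths). The
  geometry is intentionally approximate — consumers rely on atom names and
  counts, base planarity and Hoogsteen distances, all of which are tested.
- The in-plane pose of one guanine is solved numerically (Nelder–Mead from
  a fixed grid of starts) so that under C4 symmetry each N1/N2 meets the
  next guanine's O6/N7 at 2.85 Å, with soft preferences keeping O6 near the
  axis and C1′ outside. Tetrads stack at rise 3.3 Å and twist 30°.
- Antiparallel topology flips alternate tetrad levels upside down (180°
  about an in-plane axis), emulating the syn/anti glycosidic alternation of
  antiparallel stacks while preserving every within-tetrad contact, and
  odd-numbered tracts contribute their guanines in reversed order.
- Loop/flank residues go on outer arcs (radius 16 Å) between the tracts
  they connect, alternating above/below the stack; each residue is then
  pushed radially outward in 0.5 Å steps until it clears a 2.2 Å margin
  from everything already placed, which keeps every built model clash-free
  by construction. This is placement, not conformation: loop geometry is
  not meaningful beyond being finite, connected in sequence and
  non-clashing.

## Trajectory statistics

- **Superposition**: own Kabsch implementation (SVD, proper rotation
  enforced); cross-checked against MDAnalysis in the test suite.
- **RMSD** reference is frame 0, superposed over tetrad-guanine heavy atoms
  (falling back to all heavy atoms, with a warning, when no tetrads are
  found); per-residue RMSD is averaged over frames. **RMSF** is computed
  about the time-averaged structure after one re-superposition iteration;
  atom RMSF = √⟨|r(t) − r̄|²⟩, residue RMSF = unweighted mean over the
  residue's heavy atoms. Mass weighting is not used; conventions here are
  the common defaults and are what the σ√3 analytic checks in the tests
  assume (iid Gaussian jitter of σ per coordinate gives RMSF → σ√3).
- **Buckle displacement** is not a standardized quantity; here it is, per
  tetrad and frame, the mean over the four guanines of the unsigned angle
  between each base-ring plane normal and the tetrad mean-plane normal,
  folded into [0°, 90°]. It is zero for an ideal planar tetrad and reduces
  to the familiar base-pair buckle notion. A signed variant (sign from the
  projection onto the stack axis) exists because violin plots of such
  angles often show signed distributions; the unsigned mean is the default.
- **Quartiles** use the linear-interpolation convention so violin-style
  summaries are reproducible.
- Trajectory interchange is multi-model PDB only; binary MD formats are
  out of scope (convert externally).

## Synthetic world

The generators state a fixed world; their defaults are not tuned:

- Basis spectra are sums of Gaussian bands: AP = +1.0·N(295, 9) −
  0.55·N(260, 11); P = +1.2·N(260, 8) − 0.8·N(240, 6) (amplitudes a.u.,
  widths nm). Band positions carry the canonical signatures; widths were
  chosen once so the summed bands' extrema fall within ±1 nm of the
  nominal positions despite band overlap, and amplitudes give the visual
  asymmetry typical of GQ CD spectra.
- Titrations are linear mixtures with iid Gaussian noise (default paths
  use 2 % of the unit amplitude).
- Melt curves: Boltzmann sigmoid on a 25–90 °C, 0.5 °C grid (the
  instrument range of the motivating experiments), plateaus 0.05/1.0,
  width 2 °C, 1 % noise, n = 3 replicates. For the replicate-comparison
  property, replicate-level Tm scatter of 0.7 °C is used — the scale
  implied by a reported non-significant p ≈ 0.3 for a 0.7 °C difference
  at n = 3 under the pooled-variance t-test.
- Trajectories: per frame, optional random global rigid motion, then iid
  Gaussian atomic displacement with σ_tetrad = 0.2 Å for tetrad guanines
  and σ_loop = 1.0 Å for everything else (classes from `detect_tetrads`,
  not hard-coded indices). 500 frames at 100 ps spacing emulate a
  microsecond-scale sampling cadence.

What a green test establishes: that the analyses invert this stated
generative model (fraction, Tm, σ-ratio recovery within stated
tolerances). What it does not: agreement with real instrument data or
force-field dynamics — real raw spectra and trajectories for this system
are not publicly deposited, and quantities that would require them
(per-tetrad buckle tables from microsecond MD, absolute RMSF profiles) are
covered only by property-based checks on the synthetic world.

## Known limitations

- Built and edited structures are chemically crude (no minimization, no
  hydrogens, approximate sugar pucker and backbone torsions); they are
  starting points and geometric test beds, not refined models.
- The decomposition is strictly two-component; spectra with species
  outside the AP/P span show up as large residuals or out-of-range x, not
  as a third component.
- Melts near the top of the temperature range leave the upper plateau
  weakly constrained; watch the `converged` flag and Tm standard error.
- The classifier's thresholds are heuristic by design; borderline spectra
  should be decomposed, not classified.
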