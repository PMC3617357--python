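# Model and methods

## The model

`endoclone` simulates the uterine epithelium one cell at a time as a
continuous-time branching process.  Each cell carries a phenotype vector
and evolves deterministically between stochastic birth events:

* **Cycle status** `c(t) = ∫ α ds` (integral since the cell's birth):
  division at `c = +1`, apoptosis at `c = −1`.  Birth resets `c` to 0.
* **Proliferation potential** `α(t)` (cycles/month) obeys
  `dα/dt = k (α_p(g) − α) + β`: a homeostatic pull of strength `k` toward
  the programmed rate `α_p`, plus hormonal forcing `β`.
* **Generation number** `g = 1 + floor(C_max)`, where `C` is the
  lineage-cumulative cycle integral and `C_max` its running maximum —
  a telomere-like clock that never runs backwards, even while a senescent
  cell's `C` decreases.
* **Differentiation coefficient** `k = max(0, k_p(g) + Σ m_i)`: the
  programmed differentiation level eroded (or reinforced) additively by
  the mutational effects `m_i` accumulated along the lineage.  The clamp
  at 0 defines the fully de-differentiated (stem) state.

With the default parameters an un-mutated clone divides synchronously
through ten generations (peak exactly 2^10 = 1024 cells), then dies:
past the limit `α_p` is negative enough that `α* = α_p + β/k < 0` for a
normally differentiated cell (`k ≈ 4`).  Tumors arise only from lineages
whose `k` has been driven far enough down that `α* > 0` persists beyond
the programmed limit; a *detectable tumor* is a clone whose living-cell
count reaches 10^6.

## Exact event propagation

Between generation increments every coefficient is constant, so each piece
has the closed form `α(s) = α* + (α0 − α*) e^(−ks)` with
`α* = α_p + β/k`, and `c` integrates to an explicit expression.  The
implementation uses the algebraically equivalent form

    α(s) = α_p·E + β·s·(E/u) + α0·(1 − E),      E = 1 − e^(−u), u = ks
    ∫α   = (α_p·k + β)·s²·ψ(u) + α0·s·(E/u),    ψ(u) = (u − E)/u²

which is numerically stable for `k → 0` and covers `k = 0` exactly (the
linear-in-`t` regime of a fully de-differentiated cell).  Event times are
found by scanning the at-most-two monotone intervals of `c` (split at the
single sign change of `α`) and refining each bracketed crossing with
safeguarded Newton iteration to ~1e-12 months.  Generation increments
(`C_max` crossing the next integer, tie `C_max = n` ⇒ `g = n + 1`) are
processed as interior events that update `k_p`, `α_p` and re-clamp `k`.
A cell with no event before `max_sim_time` (120 months) is censored and
reported as such — with the defaults this happens only to rare senescent
stragglers whose `α*` lands very close to zero (~2–5% of normal clones
contain one).

The population engine runs a binary heap of per-cell event times (ties
broken by birth order, which for synchronous generations equals
lineage-code lexicographic order) inside a numba-compiled kernel; one
seeded legacy NumPy stream per clone makes every simulation
bit-reproducible given `(seed, parameters)`.  Per-daughter draw order at a
division is: mutation effects, inheritance noise on α, hormone β.

## The programmed proliferation curve

The source formula for `α_p` is typographically corrupted, so the curve is
reconstructed from its printed consequences and exposed as a configurable
family.  Constraints used:

* zero at the generation limit `g = 10`, positive before, negative after;
* clone peaks of exactly 2^10 with a median barely above 1024 — so the
  first post-limit generation must sit just below the division threshold;
* clone lifespans with median ≈ 576 days — senescent death is slow, i.e.
  `|α_p(11)|` is only slightly larger than `β/k_p(11) ≈ 1.23`;
* early-lineage α staying below ~10 (the printed ancestor phenotypes), so
  early `α_p` is moderate;
* a tumor phase in which cells with `k ≈ 0.3` remain viable at `g ≈ 45`
  while `k ≳ 0.45` cells die, and the within-tumor α distribution tops out
  near 18 — fixing the late-generation pull near −17.

The default **saturating** form is `α_p(g) = 17·(10 − g)/10` up to the
limit, then `−17·min(1, ((g−10)/span)^q)` with `span = 4` and the exponent
`q` anchored so that `|α_p(11)| = senescence_onset`.  `senescence_onset`
(default 1.76) is the reconstruction's one free parameter and is
calibrated against the printed clone-lifespan median — the lifespan is
extremely sensitive to it (median 1014 d at 1.70, 612 d at 1.76, 414 d at
1.80) because it sets how close senescent cells sit to the `α* = 0`
stall.  `linear` (no saturation), `clipped` (linear to −17) and
`rational` (`17(10−g)/g`) forms are available for comparison; the two
printed readings agree with the default's slope at the limit.

## Noise sources and their defaults

* **Hormone environment** `β ~ N(5, 0.5²)` per cell, constant for its
  life, truncated by resampling at ±3.4 SD (`beta_truncate_sd`).  The
  truncation is required by the printed finite lifespan range over 10^6
  clones: with unbounded draws, a ~1e-4 per-cell tail places cells
  arbitrarily close to `α* = 0` and stretches clone lifespans into
  decades.
* **Mutational effects**: two per daughter cell (count configurable,
  optionally Poisson), each drawn from a configurable family.  The default
  is `Normal(+0.004, 0.05²)` per effect — a slight mean reinforcement of
  differentiation (random hits are on average deleterious to proliferative
  fitness) with a spread that supplies the heritable variation selection
  acts on during tumor growth.  Both parameters are calibrated jointly
  against the printed normal-clone statistics (which bound the spread felt
  at `k ≈ 4`) and the printed tumor heterogeneity (median k ≈ 0.3, ~7%
  stem fraction, median α ≈ 10.3, median depth ≈ 44).  A
  `mixture` family with a rare negative-exponential tail is provided for
  exploring spontaneous immortalization of normal progenitors; it is not
  the default because any appreciable tail produces selection-amplified
  deficit cascades at the senescence boundary that contradict the printed
  clone lifespans and tumor counts.
* **Inheritance noise**: daughter `α` = parent `α` at division +
  `N(0, 0.1²)` (the paper states inheritance is stochastic but not its
  magnitude).

## Tumor-initiating phenotype runs

A run may start from an explicit phenotype `(k, α, g)` — the typical
tumor-initiating cancer cell TICC `(0.18, 3.66, 17)` or its fully
de-differentiated stem counterpart TICSC `(0, 3.66, 17)`.  The root's
mutation sum is set to `k − k_p(g)` so the differentiation equation holds,
and it carries its implied ancestry `d = g` (in this model `g` and the
division count coincide except for transient dips), so depths measured in
the grown tumor are comparable to full-history depths.

A known deviation: the reference reports a 71.7% spawn probability for the
TICC.  Within this equation set that value appears unreachable: early
extinction of a root with `α* > 0` requires `|α_p(17)| > β/k ≈ 27.8`,
which contradicts the `|α_p| ≈ 14–17` that late-generation tumor
viability pins down; across all curve forms and mutation models examined
the spawn probability is 0.87–1.0 whenever the tumor statistics are right
(the packaged defaults give ≈ 0.92).  The TICSC probability (≈ 1.0 vs the
reported ~94%) and the TICSC ≥ TICC ordering are reproduced.

## Phylogeny and statistics

Lineage codes are digit sequences over {1, 2} (the decimal `10x + i`
scheme without integer overflow).  Descendant counts per node are a single
reverse post-order sweep; `MRCA(x)` is the deepest node covering at least
`⌈x·N⌉` of the `N` detection-time cells, ties broken toward the larger
count then the lexicographically smaller code.  Which subset of the mass a
fraction refers to is not otherwise specified, so table comparisons are
approximate by construction.  MRCA phenotypes are reported at the node's
*birth*: the printed full-mass ancestor row (α = 2.95 ± 0.004) matches the
progenitor's birth α exactly and is incompatible with at-division
recording.  Newick export writes lineage-code labels with branch lengths
in days and optional bracketed phenotype comments.

Summary statistics use midpoint medians, n−1 standard deviations, raw
(non-excess) kurtosis and a 30-day month.  The per-progenitor tumor
probability carries a Garwood exact Poisson interval
`[χ²(a/2, 2x)/2, χ²(1−a/2, 2x+2)/2]/n`; tumor cohorts are compared with
the classical two-sample Kolmogorov–Smirnov test (exact supremum D,
asymptotic p with effective size `nm/(n+m)`).

## What the simulations do and do not show

The generator *is* the study system here — there is no external data.
Passing checks demonstrate internal reproduction of the reference
statistics under the reconstructed equations and calibrated noise model,
on desk-scale problem sizes (10³ clones; 10² phenotype runs to 10^6
cells; tumor statistics from the first few detected tumors).  They do not
validate the biology of real endometrium: the model has no spatial
structure, no cell–cell signalling, a constant hormone level, additive
phenotype-level mutations rather than genome sequence, and identical
independent progenitors.  The spontaneous-transformation experiment
(~3×10^8 progenitors for a handful of tumors) is out of desk scale by
design; under the default Gaussian mutation model its rate is essentially
zero, and exploring it requires the mixture family and cluster-scale
compute.

## Numerical choices

Event-time tolerance 1e-12 months (bracketed Newton with bisection
safeguard); series expansions below `u = ks ≤ 1e-3` for the relaxation
integrals; `C_max` integer-crossing tie gives the new generation; heap
ties resolved by birth order; per-clone growable arrays with a
`max_cells` guard (default 6×10^6 cells ever born, ~0.3 GB) that raises
rather than silently truncating; censoring at 120 months is recorded
explicitly and included in lifespan medians at the censor time.
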