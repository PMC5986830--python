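# Methods

## The cube and its axis policy

All input peaklists are held in a dense three-axis structure: a mapping
from (z, y, x) condition labels to one peaklist table each. Series along
one axis at fixed values of the other two are the unit of analysis, and
the first series element is always the reference experiment. The grid must
be complete — a missing coordinate is an assembly error, not a warning —
because every downstream step (padding, ratios, stacking) assumes one
table per cell.

Three restrictions keep analyses well-defined rather than merely
conventional: fitting needs a continuous, strictly increasing numeric
variable, so it is only permitted along x; a change of protein sequence
changes the residue universe, so it is only permitted along y; ΔPRE needs
exactly a (diamagnetic, paramagnetic) pair, so it runs only along z. The
policy is enforced before any computation so a misconfigured run fails in
milliseconds.

Axes of length 1 are legal everywhere; analyses that need at least two
points skip such series with a logged notice instead of failing.

## Curation semantics

Along each x-series, every residue at every point is classified:

* **measured** — a backbone row with finite shifts exists;
* **missing** — observed earlier in the series but absent here (exchange
  broadening). Under the default `carry_last` policy the last measured
  values are copied into the padded row, so bar plots can show the residue
  in red at its last known position; the `blank` alternative leaves the
  observables empty, which is safer when the derived values feed
  statistics. The copy is causal: values never come from a later point.
* **unassigned** — never observed anywhere in the series. With a supplied
  sequence (FASTA or `first:last` range), prolines are created as
  unassigned placeholders typed "P"; without one they are
  indistinguishable from other unassigned residues.

One edge case is not covered by the carry rule: a residue absent at early
points but observed later has no earlier value to carry. Such rows are
classified missing with empty observables (there is nothing causal to
copy). Residues with two conflicting backbone rows in one table are a hard
curation error naming the residue and file, since silently choosing one
would misassign data.

NH₂ sidechain entries are recognised by atom names ending in `a`/`b`
(e.g. ND2a/HD2a), excluded from backbone analyses, and kept in a parallel
table (or dropped with a logged count).

## Observables

* Δδ = δ(target) − δ(reference) per nucleus, in ppm.
* Combined CSP = `sqrt(½ (Δδ_H² + (α Δδ_X)²))`. α defaults to 0.14 with
  0.2 for glycine — the standard ¹⁵N scaling reflecting the larger ¹⁵N
  shift range — and is overridable per residue type.
* Intensity ratios I/I₀ on heights or volumes; a zero or absent reference
  produces an empty value with a warning, never an infinity.
* ΔPRE compares the observed paramagnetic/diamagnetic intensity-ratio
  profile with a random-coil prediction supplied as data. The sign
  convention is ΔPRE = predicted − observed, so positive values mark
  residues more broadened (more contact or compaction) than a disordered
  chain predicts; because the opposite convention also exists in the
  literature the sign is configurable (`dpre_sign`) and recorded in the
  output.
* The smoothed ΔPRE profile uses a running Gaussian convolution filter
  with σ = 3 residues and half-width ⌈4σ⌉ by default. Offsets are taken in
  residue-number space, weights are renormalized at sequence edges and
  across assignment gaps (so a constant profile is exactly conserved), and
  residues without values contribute nothing. The kernel parameters are
  user-settable since no single choice suits every probe width.
* Optional per-spectrum shift renormalization subtracts the apparent
  (Δδ_H, Δδ_X) of a user-chosen reference residue from the whole spectrum,
  removing buffer/temperature artefacts; it is idempotent and requires the
  reference residue to be measured at every point.

## Fitting

The default model is the Hill curve `CSPmax·xⁿ/(Kdⁿ+xⁿ)`; with n = 1 it is
the one-site non-depleting hyperbola, and the exponent can be fixed there.
A one-site ligand-depletion quadratic (exact at finite protein
concentration P₀) is available when P₀ is known, and further models can be
registered. Initialisation: CSPmax₀ = max observed response, Kd₀ = x at
half-max by linear interpolation, n₀ = 1; all parameters bounded positive;
trust-region least squares with tight tolerances (1e-14) so noiseless data
reproduce generating parameters to ~1e-10 relative.

A residue is only fit when at least four measured (not carried) points
exist. Responses whose maximum magnitude stays below a floor — by default
3× a noise estimate obtained from the median over residues of the
second-difference standard deviation divided by √6 — are still fit for
completeness but flagged `no response` so that noise-level apparent K_d
values are never interpreted. Failures (too few points, optimizer
breakdown) are reported per residue with a reason; they never raise.

## Comparative stacking

A parameter computed along one axis is re-presented along another by pure
re-indexing: each matrix cell is numerically identical to exactly one
source cell and the provenance map (column → source coordinate) makes the
operation invertible. When residue sets differ across y (different
sequences) the join is outer on author residue numbering — alignment is
deliberately *not* attempted; a report lists residues present in fewer
than all columns.

## Plotting and exports

Eight templates: extended/compacted/vertical bar plots, a Δδ_H-vs-Δδ_N
shift map, a peak-trajectory scatter, a residues × conditions heat map,
the ΔPRE overlay (predicted vs. observed ratio, raw and smoothed
difference) and a per-residue evolution grid (with fitted curves overlaid
when available). Colour semantics everywhere: black measured, red missing,
grey unassigned, prolines labelled "P", optional red significance
threshold line. The significance threshold is a user-set constant only; no
automatic σ-based rule is imposed. Every figure is written with a sidecar
CSV containing exactly the plotted values; tests (and users) audit
sidecars, never pixels.

Chimera attribute files use the documented "Define attribute" grammar with
values at ≤6 significant digits; the attribute name is validated against
the viewer's own rules. An exporter registry leaves room for other viewer
dialects. All output lands in `output/<z>/<y>/<analysis>/` with a
`manifest.csv` listing every file; a non-empty output root is refused
unless overwrite is requested, and re-running a configuration reproduces
manifests and sidecar CSVs byte-for-byte.

## Synthetic data

The titration generator emulates a seven-point ligand titration
(0, 25, 50, 100, 200, 400, 800 µM) of a 100-residue protein in fast
exchange: δ(x) = δ_free + f_bound(x)·Δδ_max with f_bound = x/(K_d+x);
30 responding residues with K_d ∈ [50, 300] µM, Δδ_max,H ∈ [0.03, 0.12]
ppm and Δδ_max,N ∈ [0.15, 0.60] ppm; residue 22 disappears from point 4
onward; five prolines are never observed. Noise: Gaussian σ = 0.002 ppm
(¹H) and 0.02 ppm (¹⁵N) on shifts, log-normal 2% on heights — typical of
well-resolved HSQC data. The paramagnetic generator produces a
diamagnetic/paramagnetic pair whose true intensity-ratio profile is a
Gaussian broadening well at the probe site on a 0.95 baseline, times
optional "deviation regions" of extra broadening; the predicted profile
contains only the coil part, so the ground-truth ΔPRE is exactly the
deviation signal. All generators are deterministic given their seed, and
every emitted file (in any supported dialect) parses back through the
package's own readers without warnings.

What the generators do **not** emulate: peak overlap, lineshape and
baseline distortions, titration-dependent linewidths, chemical exchange
between fast and slow regimes, and assignment errors. Passing tests
therefore demonstrate correctness of the arithmetic, curation and
book-keeping on idealised data — not robustness to the pathologies of
real spectra, which remain the curator's responsibility.

## Numerical choices and problem sizes

Peaklist dialect details (column orders, comment markers) are frozen by
the generator/parser pair and covered by round-trip tests; numbers parse
in the C locale with scientific notation accepted; canonical CSVs write
shortest-round-trip decimals and are re-read with exact `float()`
conversion so round trips are bit-faithful. Test and verification runs use
the generators' default sizes — 100 residues, 7 titration points, 10
variant pairs, 50-residue fitting panels, 10⁴-point formula checks —
which exercise every code path while keeping the full suite around a
minute on a single CPU.

## Known limitations

Sparse cubes (absent coordinates) are rejected rather than tolerated.
ΔPRE is computed from intensity ratios only; conversion to Γ₂ rates or
distances, linewidth-based PRE and relaxation fitting are out of scope.
No global (shared-K_d) fitting across residues, no bootstrap error
estimates, no automatic assignment transfer or peak tracking between
spectra, and no statistical tests between stacked columns. The Ansig
fixed-width dialect is recognised by name but intentionally unsupported.
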