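# Methods

## The %Δ PTM/site metric

Site-level MS evidence is a table of non-negative quantities keyed by
(protein, site, modification, condition, replicate). For one condition pair
(vehicle, treated), replicate quantities are averaged *within* each
condition first — the replicates are technical, so the condition mean is
the estimand — and the percent change of the treated mean relative to the
vehicle mean is computed per (site, modification). A protein's (or a
modification's) %Δ PTM/site is the unweighted mean of its valid site-level
changes; the unweighted mean normalizes proteins of different site counts
onto a common per-site scale. An intensity-weighted variant was considered
and rejected as the default because site intensities span orders of
magnitude and a single bright site would dominate the protein value; the
`statistic="sum"` option provides the summed alternative.

Degenerate cases: a site with vehicle mean 0 but treated signal has no
defined percent change from zero and is recorded as a *new-site* sentinel,
excluded from averages by default (a pseudo-count option, e.g. +0.5, turns
these into large finite changes instead); a site at 0 in both conditions is
null. A protein with no valid site carries an insufficient-data marker
(NaN) rather than 0, and sign censuses treat it as "unchanged/no data".

Net signs use a zero tolerance of 1e−9 percent: exact zeros are meaningful
only for noiseless (synthetic) data, and any real measurement off zero by
more than that is a genuine direction.

Correlation analyses (young-vs-old per-protein changes; centrality vs
change per arm) report Pearson's r, the least-squares line, and a 95%
percentile bootstrap interval on the slope from 1000 case resamples under
a fixed seed. Bootstrap-of-cases was chosen over residual resampling
because the x values (per-protein changes) are themselves random.

## Network centrality and calibration

Eigenvector centrality is computed by power iteration on the unweighted
adjacency of the *full* network, with a unit shift (x ← (A + I)x,
renormalized each step). The shift leaves eigenvectors unchanged while
making the dominant eigenvalue strictly largest in magnitude, so the
iteration converges on bipartite graphs (a plain iteration oscillates on a
star graph). Convergence: L1 change below n·tol with tol = 1e−10, at most
1000 iterations, uniform non-negative start (which also fixes the sign of
the eigenvector). The final vector is normalized to unit Euclidean norm.
On disconnected graphs the component with the largest spectral radius
carries essentially all mass — the intended behavior when a large
reference network dominates.

The detected-protein subnetwork is the induced subgraph on the detected
ids; its centrality values are *exactly* the full-network values (no
recomputation), keeping them numerically calibrated to the whole-proteome
scale. Edges are thresholded at a STRING-style combined score of 400
("medium confidence") by default and treated as unweighted thereafter: the
edge list contributes topology only, and no principled weighting scheme
exists for mixing confidence with influence.

Louvain community detection (networkx implementation, resolution 1.0,
seed 0) runs on the largest connected component of the subnetwork only;
smaller components are not force-assigned labels. Community labels are
re-indexed by (size desc, smallest member) so runs are reproducible, and
the partition's modularity is reported. No merging is applied if more
than a handful of communities emerge — the community count is a property
of the data.

## The electrostatic stability model

The model reduces a protein to its counts of Arg+Lys (positive), Asp+Glu
(negative) and His (variable) residues and its length N. Histidine enters
as an *expected* fractional charge — 0.4 in the native state, 0.1 in the
denatured state — rather than a per-molecule integer; this matches the
summed-count form of the net-charge expressions and keeps the model
deterministic. Ambiguity codes (B, Z, X, U, O) count toward N but carry no
charge, the conservative choice for a composition-only model.

Native and denatured radii of gyration follow Flory scaling
(R_n = 2.24·N^0.392 Å, R_d = 1.927·N^0.598 Å; the denatured chain is more
expanded for any N ≥ 3). The folding free-energy change on a ±1 charge
step is the difference of screened Born-like self-energy terms of the two
states, in kT, with I_b = 7.13 Å and κ = 0.03 Å⁻¹ emulating cytoplasmic
salt at 37 °C. Temperature never appears explicitly because everything is
expressed in kT.

The signed ΔΔG is kept verbatim (denatured term minus native term) for
both charge_delta = +1 and −1; the *susceptibility* used for scoring is an
aggregation of the two magnitudes (default: their mean). Averaging signed
values instead would collapse to a charge-independent constant — the
(±2Q) terms cancel — contradicting the charge-dependent shading the
susceptibility map is meant to display, so magnitudes are the meaningful
summary. `max`, `plus` and `minus` aggregations are provided.

The proteome map evaluates the model per FASTA record, attaches a Gaussian
KDE density over the (Q_n, N) plane (quartile level sets exported as
contour levels), and flags proteins in the top quartile of the
susceptibility distribution. The Q_n (native) axis is used for the charge
dimension because the native state is the physiologically displayed one;
this is switchable. Identical-sequence degenerate inputs produce a warning,
NaN densities and an all-False flag.

## Composite sensitivity score

Over the scored set P, RSS = minmax(|ΔΔG|) · minmax(E) and
CSS = minmax(RSS). Min–max normalization requires at least two distinct
values and is invariant under positive affine transformations, so the CSS
*ranking* is unit-free; exactly the argmax rows reach 1.0 and the argmin
rows 0.0. Percentile subsets use inclusive ties (no protein is dropped on
float equality) and a deterministic (css desc, id asc) ordering.

P defaults to proteins with a computable susceptibility, a calibrated
centrality, *and* at least one PTM observation ("ptm-mapped"); the
alternative "network" mode scores every subnetwork protein. Both are
legitimate reads of "all proteins represented in the study" and the choice
materially changes percentile cutoffs, so it is a config switch rather
than a hidden default. Proteins absent from the interaction network have
no centrality and are excluded from P (they remain in the stability and
PTM tables with null annotations).

## Synthetic data: what it emulates, what it does not

The generator emulates the study design the pipeline targets: a two-age,
two-arm comparison (young/old × vehicle/treated) with 3 technical
replicates; per-protein planted %Δ effects, drawn by default from
N(−25, 15) in the old arm and N(+10, 15) in the young arm (clipped to
[−95, 200]) so that oxidative-PTM loss dominates in old and gain in young;
site quantities with vehicle expectation 1000 counts under Poisson noise
(count-like data; `noise_scale=0` switches to exact expectations for
truth-recovery tests). Proteomes sample per-protein lengths uniformly on
[60, 1200] residues and charge-class fractions on ranges around the
composition of real globular proteins (positive 8–16%, negative 8–16%,
His 1–4%); non-charged positions are drawn uniformly from the 15 remaining
standard amino acids, since charge classes are the only sequence property
the stability model consumes. Networks are Barabási–Albert
preferential-attachment graphs (m = 3), optionally with planted hubs wired
to random partners until their degree is ≥10× the median; edge confidences
are uniform on [400, 1000). The demo scale (2000 proteins, 500 detected,
5 hubs) keeps a full run in seconds while leaving the subnetwork large
enough for non-trivial community structure.

What the generator does *not* emulate: peptide digestion and spectra,
site-localization uncertainty, missing-value structure of real MS runs,
correlated modifications on one protein, degree-correlated detection bias,
or any relationship between a protein's sequence and its network position.
Passing truth-recovery tests therefore demonstrates the *analytic chain*
is correct, not that the biology of a real joint proteome would be
recovered at these noise levels.

## Numerical choices and limitations

- Power iteration: tol 1e−10, max_iter 1000, uniform start; non-convergence
  raises with advice rather than returning a stale vector.
- Bootstrap: 1000 resamples (500 in the demo pipeline for speed), percentile
  interval, seeded.
- Louvain is a greedy heuristic; optimality is only guaranteed (and tested)
  on tiny graphs where exhaustive search is feasible.
- The stability model is composition-only: no structure, no pKa shifts, no
  per-site chemistry. Two proteins with equal composition are
  indistinguishable regardless of fold.
- Exact reproduction of the published mouse-joint score table would require
  the original MS dataset and the matching STRING snapshot; the packaged
  top-20 reference table anchors census and ranking semantics only.
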