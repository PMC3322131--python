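# Methods

## Reference-anchored fragmentation

All region coordinates are 1-based inclusive residue indices on the ungapped
reference sequence (the packaged table uses the rat TRPV1 numbering,
N-terminal 1–432 through PIP-2 778–819, 29 regions in total; overlaps such as
the cholesterol-binding CRAC element inside TM-5 are allowed). The package
assumes one global multiple alignment containing the reference; it does not
align. A column map sends each reference residue to its alignment column, a
region to a column span, and a species' slice to its row over that span.
Column-span semantics are used deliberately: a non-reference insertion inside
the span (a column where the reference is gapped) belongs to that species'
slice, because the biological region is "whatever this species carries
between the mapped endpoints".

Coverage of a slice is the fraction of span columns holding a real residue
(neither gap nor `X`) in that species. Slices below `min_coverage` are
excluded per region and logged. The default `min_coverage = 0.5` keeps
half-resolved partial sequences in play — the workflow expects fragmentary
database entries and prefers per-region exclusion over discarding a species
globally. Regions that extend past a truncated species' row simply score low
coverage; only a region extending past the *reference* is an error.

## Conservation statistic

The distance is the uncorrected amino-acid p-distance with pairwise
deletion: for one pair, drop every column where either member shows `-` or
`X`, then `p = differing / compared`. `X` is treated as missing rather than
as a mismatch so that sequencing gaps do not masquerade as divergence. No
multiple-hit correction (Poisson, JTT) is applied — the statistic is meant
as a rank measure of conservation, and corrections would not change ranks
for the divergences involved. A pair with zero comparable columns carries an
undefined `p` (flagged, excluded from summaries).

Per region, all k(k−1)/2 pairwise distances form the distribution of
interest; the median is the headline number (lower = more conserved) with
quartiles for boxplots. Pair-level variance is available from a column
bootstrap (resample columns with replacement, recompute `p`; default 1000
replicates, seeded). Regions are compared with the Kruskal–Wallis rank test:
tie-corrected `H`, `df = k − 1`, chi-square p-value, with a seeded
Monte-Carlo permutation p available for very small groups. When every pooled
observation is identical the statistic is reported as `H = 0`, `p = 1`
(no rank evidence) rather than as an error. Note that the pairwise
distances entering one group are not independent (each species appears in
k−1 pairs), so the chi-square p-value is an approximate, descriptive check
of separation rather than an exact test — this mirrors how such comparisons
are commonly made on distance matrices.

## Helical wheel and arc coverage

Residue *i* projects to angle `(i−1)·360·turns/steps mod 360`, position 1
anchored at 0°. Two parameter sets matter: the study setting steps 18 /
turn 7 (140°/residue), which is the package default, and the canonical
α-helix steps 18 / turns 5 (100°/residue, 3.6 residues per turn). Both are
exposed; the choice changes the projected geometry and therefore clustering
statistics, which is why it is an explicit parameter everywhere.

Positive residues are K, R and H for wheel statistics (histidine is plotted
even though it is mostly neutral at pH 7.4; see the charge module). Wheels
from all species of a region are superimposed by pooling their positive
residues with multiplicity. Clustering is quantified as best-arc coverage:
the maximal fraction of pooled angles inside an arc `[a, a+w)` of fixed
width `w`, maximized over `a`. Since coverage as a function of the start
angle only changes when the arc boundary crosses a data angle, evaluating
candidate starts at the pooled angles themselves finds the exact discrete
optimum; wrap-around arcs are handled and ties break to the smallest start
angle. Because position 1 is always at 0° and the arc search is
rotation-invariant, no manual re-anchoring of wheels is needed. A pooled set
with no positives yields a flagged undefined result, not an exception.
Quadrant counts use the four bins `[0°,90°), …, [270°,360°)`.

## Composition, net charge and pI

Composition pools residue counts across a region's retained species; `X`
and gaps are excluded from the denominator (they are missing data, not
residues). Absence counts report how many species carry no residue from a
query set (e.g. no E or D) among species with non-empty slices.

Net charge is the Henderson–Hasselbalch sum over basic groups (K, R, H side
chains, N-terminus) and acidic groups (D, E, C, Y side chains, C-terminus).
The isoelectric point is found by bisection on [0, 14]: the charge is
strictly decreasing in pH so the root is unique; 60 halvings shrink the
bracket to ~1e-17 pH units, and the returned root always satisfies
|charge| < 1e-4 (asserted at run time). Terminal groups are included even
for internal region peptides — the convention of standard pI calculators
fed a pasted subsequence, and the right one for comparing against numbers
produced that way. Two named pKa sets ship, `bjellqvist` (default) and
`emboss`; basic peptides shift by a few tenths of a pH unit between scales,
so cross-tool pI comparisons should allow ±0.2.

## Motif grammar

The basic-stretch grammar is a string over `{+, X}` (canonical 21-mer
`+XXX+XX++XX+XX+XXXXXX`, regenerable from its `+` positions
{1,5,8,9,12,15}). Defaults: `+` accepts {K, R} — histidine is excluded
because the stretch selects against it — with a {K, R, H} preset for
wheel-consistent scans; `X` forbids {D, E, P}, i.e. acidic residues and the
explicitly named helix breaker, with a stricter {D, E, P, G} preset.
Matching is per-position; the satisfied fraction supports fuzzy scans
(threshold 1.0 by default; ~0.8 is a reasonable cross-family screen).
Scanning evaluates every offset and sorts hits by fraction, then offset. No
probabilistic model (PSSM/HMM) is attempted — the grammar is deterministic
by design.

## Molecular clock

Each lineage comparison contributes one point: 100 × mean pairwise-deletion
p-distance over its stated sequence pairs, against the divergence time in
MY. Ordinary least squares (no weighting, no errors-in-variables) fits the
line; with two points the fit is exact. The time-axis crossing is the
apparent origin of the protein; the Y-intercept at time 0, divided by the
slope, reads out how many MY of further change at the current pace would be
needed to reach a fully settled sequence. Divergence times are user input
via the manifest; the documentation uses a calibration of ~90 MY (mammal
radiation), ~350 MY (bird–amphibian) and ~400 MY (fish–amphibian) as a
worked default, which is a documentation choice, not a claim about any
particular dataset. Whether to include the (0, 0) self-comparison anchor is
an explicit flag (`anchor_zero`).

## Synthetic families: what they emulate, and what they do not

The generator produces a star phylogeny: every tip mutates independently
from one ancestor, site `j` with probability `base_rate × relative_rate(j)`,
substituting to a uniformly random different residue. Regions set
`relative_rate` over their spans (later list entries override earlier ones
where regions overlap); a motif region constrains `+` sites to {K, R} in the
ancestor and under substitution (with `relative_rate` additionally scaled by
`motif_conservation`, default 0.1) and keeps excluded residues out of `X`
sites. Indels occur only outside declared regions, half deletions, half
single-residue private insertions, and are emitted directly as gap columns
of the true alignment, so region extraction is testable without an aligner.
Tip 0 is emitted indel-free to serve as a complete reference, mirroring the
complete template sequence a real analysis anchors on.

Defaults describe a vertebrate-family-sized problem: 32 species, 839
residues (the reference length), `base_rate = 0.3` expected substitutions
per site per tip — giving full-length pairwise p-distances around 0.4,
typical of a vertebrate-wide membrane-protein family — and `indel_rate = 0`
unless exercising gap handling.

What passing tests on these families demonstrates: correct coordinate
mapping through gapped alignments, correct pairwise-deletion counting,
recovery of a known conservation ranking, exact motif preservation, and
clock-slope recovery from divergences proportional to time. What they do
not demonstrate: behaviour under realistic substitution processes
(exchangeability matrices, rate heterogeneity within regions), tree-shaped
covariance between species (a star has none — real phylogenetic structure
makes pairwise distances more correlated, not less), alignment error (the
true alignment is given), or the charge geometry of real helices — in
particular, planted `+` positions need not project into one sector under a
given wheel parameterization, so synthetic arc-coverage values quantify the
planted pattern's geometry under that projection, nothing more.

## Numerical and design choices

- Region pairwise distances are computed over aligned region columns, not by
  re-aligning each slice pair: one global MSA defines comparability, and
  pairwise deletion stays well-defined.
- Kruskal–Wallis and OLS are delegated to scipy/numpy; the surrounding
  statistics (p-distance, bootstrap, arc search, pI bisection, grammar) are
  implemented here.
- TSV floats are written at 6 significant digits; pipeline outputs contain
  no timestamps, so a rerun with the same config and seed is byte-identical.
- The pipeline seeds every stochastic step (bootstrap, permutation) from the
  single run seed recorded in the run manifest.
- Degenerate inputs prefer flags over exceptions when the condition is a
  legitimate data state (no positives on a wheel, a pair with no comparable
  columns) and exceptions when it is a caller error (empty pattern, region
  past the reference, fewer than two sequences).

## Known limitations

- p-distance saturates for deep divergences; ranks remain meaningful,
  absolute values do not.
- The Kruskal–Wallis p on pairwise distances ignores pair non-independence
  (see above).
- Arc-coverage percentages depend on the wheel parameterization; compare
  values only at matching steps/turns.
- pI values are scale-dependent (±0.2 between common pKa sets) and ignore
  structural pKa shifts.
- The clock is a two-parameter OLS on few points; no confidence beyond OLS
  residuals is offered, and calibration times are the user's responsibility.
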