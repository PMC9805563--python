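# Methods

## The model and the three search strategies

All three algorithms perform the same agglomeration.  With `n` live nodes,
row sums `S(i) = Σ_k D(i, k)` and criterion
`Q(i, j) = (n − 2)·D(i, j) − S(i) − S(j)`, the minimizing pair `(x, y)` is
joined into `z`, branch lengths are estimated, and the matrix contracts via
`D(i, z) = (D(x, i) + D(i, y) − D(x, y)) / 2` with `S` repaired incrementally
in linear time (`S_i ← S_i − D(x,i) − D(i,y) + D(i,z)`).  They differ only in
how the minimizing pair is found:

- **canonical**: full scan of all pairs, O(n²) per iteration.  The oracle.
- **dynamic (DNJ)**: per-row cached minima + running-minimum sweep (below).
  Exact; O(d·n²) with `d` the rows rescanned per iteration.
- **heuristic (HNJ)**: joins the cached minima directly, no sweep.  O(n²)
  total; exact only when no join ever exposes a better partner in a row,
  which is guaranteed for strictly additive matrices.

### Why the dynamic skip is lossless

On non-negative distances satisfying the triangle inequality, contracting the
matrix can only weaken each row's best criterion: expanding the
post-join criterion of any surviving pair shows the change is
`(D(x,y) + (D(x,i)+D(i,k)−D(i,k)) + (D(i,y)+D(y,k)−D(i,k))) / 2 ≥ 0`-shaped,
i.e. bounded below by triangle inequalities.  Hence a cached row minimum,
taken before a join, is a *lower bound* on that row's criteria after it.  The
sweep walks rows in descending storage order keeping a running minimum `M`;
a row whose cached bound cannot beat `M` (`Q_i ≥ M`, strict test `Q_i < M`
for the rescan) cannot contain the global argmin and is skipped without loss.
Rescanned rows refresh their cache to the exact row minimum, so the returned
pair always comes from an exactly-scanned row.  As an optimization `M` is
initialized from the just-scanned new-node row rather than +∞, since the new
node frequently hosts the next minimum.

The lower-bound argument assumes metricity, and contraction does not
obviously preserve it.  The implementation therefore treats oracle
equivalence as ground truth and offers `audit_lower_bound` / `audit_sweep`
diagnostics that compare caches and the sweep result against brute force each
iteration, *recording* violations in the run report rather than asserting
them away.  Across all seeded metric and additive suites in the tests and the
acceptance script, zero violations and zero sweep mismatches are observed.

### Cache repair (DNJ) vs cache update (HNJ)

After each join DNJ scans the new node's row once and, for every row below
it in storage order, folds in the single new-node term
`(n−2)·D(i,z) − S_i − S_z` — linear work.  Rows whose remembered partner was
consumed keep their (still lower-bounding) value with the partner marked
stale; staleness is harmless because selection only ever happens from
freshly scanned rows.

HNJ replaces the sweep with a two-term minimum per row: the remembered
partner's criterion, *re-evaluated* with the current `n` and `S`, against the
new node's term.  Re-evaluation (rather than carrying a frozen scalar) is
deliberate: the cached pair's criterion drifts as row sums shrink, and a
frozen scalar would compare quantities from different iterations.  The cache
therefore always holds the true current criterion of one concrete live pair
per row — just not necessarily the row optimum.  When a row's remembered
partner was consumed by a join and the new node's term does not replace it,
that single row is rescanned (at most every row once per iteration, so the
quadratic total survives; observed staleness rescans are a small fraction of
rows per iteration).

### Storage layout and tie-breaking

Rows occupy fixed slots; a join retires both slots and re-uses the *lower*
one for the new node, so no row ever moves.  This was chosen over compacting
the matrix by relocating the last live row: relocation changes which pairs
belong to which row of the lower triangle, which silently invalidates the
lower-bound coverage of cached row minima (a pair can migrate from a scanned
row into a row whose cache never saw it).  With fixed slots the lowest slot
is always the live one, caches cover exactly the pairs they were computed
over, and all three algorithms share one storage order.  The cost — the
dense triangle does not shrink in memory — is irrelevant at the problem
sizes this implementation targets.

Ties in `Q` break to the smallest row slot, then the smallest column slot.
Canonical NJ applies this rule globally.  The dynamic sweep's strict rescan
test means a *stale* cache that ties the running minimum is skipped (safe:
the minimum is already achieved by a refreshed row), so under exact ties the
dynamic choice can differ from the canonical one among tying pairs; on the
continuous random inputs used throughout, exact ties have measure zero, and
the oracle-equivalence suites confirm identical trees.

### Branch lengths and termination

The usual Studier–Keppler estimates:
`b_x = D(x,y)/2 + (S_x − S_y)/(2(n−2))`, `b_y = D(x,y) − b_x`.  Negative
estimates are reported as computed by default — clamping silently changes
trees and would break oracle comparisons — with an opt-in
`clamp_negative` mode that clamps each length to 0.  The criterion is
degenerate at `n = 3` (all pairs tie), so the loop stops at three nodes and
solves the three spoke lengths from the pairwise distances exactly;
`n = 2` splits the single distance evenly.

## Precision modes

Distances can be stored as float64, float32, or quantized 2-/1-byte cells
with a dequantization factor `scale` (`distance = cell × scale`).  `S` and
`Q` are always accumulated in float64 whatever the storage mode.  Default
quantization uses the full level range, `scale = max(D)/L` with `L = 255` or
`65535` and round-half-up cells, giving per-cell error ≤ `scale/2`;
an explicit `scale` may be passed instead, and the CLI picks `scale = 1`
automatically when all distances are integers within range so that
integer-valued matrices (SNP or Hamming counts) embed exactly and produce
trees identical to double precision.  Newly formed distances in quantized
runs are snapped back to the grid, saturating at the top level and flooring
at zero.  Round-half-up was chosen as the deterministic nearest-level rule.

## Input handling choices

- Relaxed lower-triangular PHYLIP: first whitespace token is the name (no
  10-column limit), remainder of the line the distances; blank lines are
  ignored.  Full-square input is checked for symmetry to `1e-6·max|D|`
  (formatted floats are rarely bit-symmetric) and the lower triangle kept.
- gzip is detected from the 0x1f 0x8b magic bytes, never the file name.
- Newick input is treated as unrooted (a degree-2 root is suppressed), and
  trees convert to additive matrices via patristic path sums.
- Robinson–Foulds is normalized by the total number of nontrivial
  bipartitions in both trees (`2(n−3)` for two binary trees); the `--threads`
  flag is accepted for interface parity but execution is serial — results
  are defined to be identical to the serial reference either way.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed), NumPy PCG64:

- `additive_matrix`: patristic distances of a random binary tree (topology
  grown by uniform edge attachment; lengths i.i.d. U(0.1, 2.0) by default —
  comfortably positive, within one order of magnitude, so trees are
  resolvable but not trivially separated).  Emulates tree-derived inputs
  such as surveillance pipelines that export trees later converted to
  matrices.
- `metric_matrix`: Euclidean or cosine distances of standard-normal points
  (default dim 8) — metric but far from additive.
- `clustered_matrix`: Gaussian mixture with centers at 10σ separation —
  the hierarchically structured regime where the dynamic search rescans few
  rows (observed ≈ 14 of ~1000 mean live rows per iteration at n = 2000).
- `star_matrix`: all distances equal — the adversarial regime where every
  criterion ties, caches go uniformly stale after each join, and rescans per
  iteration approach the live row count (observed ≈ 128 of ~128 at n = 256).

These fixtures do not emulate real sequence-derived matrices (no Jaccard
k-mer structure, no SNP saturation, no missing data, no imbalanced-clade
shapes typical of outbreak data).  Passing suites therefore demonstrate the
algorithmic contracts — oracle exactness, lower-bound soundness, rescan
regimes, format fidelity — not biological accuracy of NJ trees on any
particular dataset.

## Numerical choices

- Branch-length agreement between trees is measured edge-by-edge on
  bipartition-keyed length maps, tolerance 1e-9 in the oracle suites.
- Lower-bound audits allow slack `1e-9·max(1, |Q|)` for float accumulation.
- Four-point and triangle audits are brute-force (O(n⁴)/O(n³)) and reserved
  for small n in tests.
- Problem sizes in the suites — 200 oracle matrices up to n = 64 additive /
  n = 40 metric, HNJ additive up to n = 128, rescan regimes at n = 2000
  clustered and n = 256 star — were chosen to exercise every code path and
  both search regimes while keeping the full suite in seconds.

## Known limitations

- No on-disk or memory-mapped matrix mode; the dense working matrix is held
  in RAM, so the practical ceiling here is ~10⁴ taxa, not 10⁶.
- Single-threaded; the repair loops are vectorized but not parallelized.
- HNJ's tie-breaking and staleness policy on non-additive data are this
  package's stated choices; other implementations of the same idea may
  legitimately produce different (equally approximate) trees there.
- Exact criterion ties can resolve differently between the dynamic sweep and
  the canonical scan (see tie-breaking above); only continuous-input
  equivalence is claimed.
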