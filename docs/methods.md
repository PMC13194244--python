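# Methods

This note records the models, numerical choices and known limitations of
`phylohaar`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees and conventions

All computation hangs on a *planted* binary tree: the root ∘ has degree
one, every other interior node has exactly two ordered children, and the
edge below ∘ (the planted edge) contributes shared covariance to all
leaves.  Leaves are ranked left-to-right (postorder), so every subtree
occupies a contiguous leaf-rank interval — the property that lets
wavelet supports be stored as three integers and lets all wavelet
coordinates of a vector come out of one cumulative-sum pass.

Two depth conventions coexist and differ by exactly 1 per leaf:

* **planted** — edge-distance to ∘.  Used by the covariance diagonal and
  by the sparsity bound `1 − ξ ≤ 2(EPL+1)/n² − 3/n` (with the unplanted
  EPL the bound is violated already on the balanced 4-leaf example:
  0.375 < 10/12; with the planted EPL it holds, 0.875 ≥ 10/12).
* **unplanted** — edge-distance to ∘'s child, with a one-leaf tree at
  depth 0.  Used for all moment work, matching the recursion base
  E(L₁) = 0.

Newick input is parsed by dendropy and converted to the planted form: a
branch length on the outermost group becomes the planted-edge length
(default 0 when absent), missing branch lengths default to 1,
unifurcations are contracted with lengths summed, and multifurcations are
resolved into a left-to-right cascade of zero-length edges.  The cascade
leaves the covariance matrix bit-identical (zero-length edges contribute
nothing to ancestor-path sums) but is a modelling choice for the wavelets
themselves: the Haar-like basis of the resolved tree is *not* the
k-regular wavelet family of the original polytomy, and split-level
statements at a resolved polytomy refer to the artificial binary cascade.

## Ensembles

The critical beta-splitting law q(n, i) = n/(2 h_{n−1} i(n−i)) is sampled
exactly through the mixture identity 1/(i(n−i)) = (1/i + 1/(n−i))/n: draw
J with P(J=j) ∝ 1/j by inverse-CDF against a cached harmonic-number
table (binary search, O(log n)), then return J or n−J on a fair coin.
The uniform model means uniform over *ordered* binary shapes, i.e. the
Catalan split law q(n,i) = Cat(i−1)Cat(n−i−1)/Cat(n−1), evaluated in log
space; leaf-labelled uniformity is out of scope.  Default edge lengths
are 1 (all zero-pattern results are length-independent); an exponential
rule and a user callable are provided, applied to every edge including
the planted one.

An exhaustive enumerator lists all Cat(n−1) ordered shapes with exact
rational probabilities for n ≤ 12.  It is the oracle against which both
the samplers (Monte-Carlo moments within 4σ) and the moment recursions
(exact rational equality for n ≤ 8) are tested.

## The sparse transform

The transform never materializes C.  With S(w) the sum of ℓ(e)|L(e)|²
over the edges in the subtree hanging from w (including w's parent edge),
one postorder pass gives S, and then

* λ_∘ = S(top)/n,
* λ_v = c₋(v)² S(v₋) + c₊(v)² S(v₊),
* entry(u, v) = φ_u[block containing L(v)] · (c₋(v) S(v₋) − c₊(v) S(v₊))

for u a strict ancestor of v or u = ∘.  Off-diagonal entries are
enumerated by ancestor walks, so the structural pair count is at most
twice the sum of interior-node depths and the total cost is
O(n + pairs).  The closed form is validated *only* against the dense
oracle ΦᵀCΦ (200 seeded random trees, both ensembles, unit and
exponential lengths, max entrywise error < 10⁻¹⁰); no balanced-
cancellation detection is attempted beyond the numerical tolerance.

Because "sparsity" is used in two senses, `sparsity_stats` exposes both:
**structural** counts pairs with disjoint wavelet supports as vanishing;
**numerical** additionally counts stored entries with |value| ≤ tol
(default 10⁻¹²).  ξ is the *vanishing* off-diagonal fraction — the
convention consistent with the bound and with the limit ξ → 1 — and the
complementary nonzero fraction is reported alongside.

## Moment recursions

The depth recursions condition on the top split (i, n−i) and on the side
containing the uniformly chosen leaf (probability i/n), using
q(n,i) · 2i/n = 1/(h_{n−1}(n−i)):

    E(L_n)   = 1 + (1/h_{n−1}) Σ E(L_i)/(n−i)
    E(L_n²)  = 1 + (1/h_{n−1}) Σ [2E(L_i)+E(L_i²)]/(n−i)

The second-moment recursion is derived here rather than quoted, so it is
gate-kept by a test requiring exact rational agreement with the
exhaustive enumerator up to n = 8 before anything downstream uses it.
The two-leaf product E(Z_n) follows the ancestor-plus-convolution
recursion with weights (i−1)/(n−i), base E(Z₂) = 1, and exchangeability
converts depth moments to EPL moments: E(EPL) = n·E(L_n),
E(EPL²) = n·E(L_n²) + n(n−1)·E(Z_n).

**Arithmetic.**  Rationals are exact but their denominators grow like
lcm(1..N), making the O(N²) recursion effectively cubic; double
precision keeps ~10⁻¹² relative accuracy on these positive, well-scaled
sums.  The engine therefore runs exact `Fraction` arithmetic up to a
configurable cap (default N = 128 — far beyond the n ≤ 8 oracle gate)
and float64 beyond, where the quantities under study (asymptotic
relative errors ≥ 10⁻⁵) dwarf the rounding.  `epl_moments_exact(8192)`
takes well under a second.

**Asymptotics.**  The expansions are evaluated with mpmath at 50 digits;
the constants b₀, C₂, C₁, B₁ are computed from their printed closed forms
in ζ₂, ζ₃, ζ₄, γ.  `epl_expansion_coefficients` returns the expansions
term-by-term so the variance cancellation (the n²log⁴ and n²log³ terms of
E(EPL²) and E(EPL)² coincide) and the internal consistency
Var-coefficients = second-moment − mean² can be asserted at coefficient
level rather than read off noisy numerics.

## Distance and permutation test

d_h uses only the diagonal λ_v even when off-diagonal transform entries
are nonzero — definitional, not an approximation toggle.  Coordinates,
reconstructions and per-resample statistics all run through the
leaf-interval cumulative-sum pass, so a resample costs O(n) regardless of
how many components are examined.

The test pools a+b, redraws a' ~ MVH(|a|; a+b) (numpy's sequential
conditional "marginals" method, which realizes the distribution exactly;
correctness is asserted distributionally by goodness-of-fit, not by
algorithm identity), sets b' = pool − a', and streams exceedance counts
in chunks — no resample matrix is ever stored.  A work budget
(resamples × leaves, default 2·10¹⁰) refuses runs that cannot finish,
pointing at ε, an explicit N, or the budget itself.

Two p-value estimators are provided.  The default `add_one`,
(1 + #{≥ observed})/(N+1), can never return 0 and is the calibrated
choice under ties; `strict`, #{> observed}/N with a 1/N floor and a
`floor_flag`, reproduces discovery-probability reporting, where a
zero-exceedance component under a Bonferroni factor m is reported as the
bound m/N.  Both Bonferroni and Benjamini–Hochberg corrections are
exposed and neither is privileged; BH is delegated to statsmodels and
unit-tested against a hand-computed step-up example.

## Synthetic data

The generator draws each sample multinomially at depths |a| = |b| = 10⁴
(defaults) from a leaf composition, Dirichlet(1) by default — i.i.d.
reads from a fixed environment distribution, which is the null the test
targets; pooled without-replacement resampling is the test's device, not
the data model.  The alternative moves mass ε across one chosen split in
environment a only, scaling each block proportionally so the composition
still sums to one; in expectation only wavelets whose supports meet that
split move.  The calibration study (50-leaf critical tree, 500
replicates, N = 2000 resamples) checks per-split type-I error against
exact binomial 99% acceptance bands; since ~49 splits are checked against
individual 99% bands, the acceptance rule pre-registers the designated
top split in band, ≥ 90% of splits in band, and the mean rate in a
tighter band.  The power study fixes a *uniform* composition so block
masses are deterministic and the grid ε ∈ {0, 0.05, 0.1, 0.2} is always
feasible (a Dirichlet draw can put less than ε of mass on the shifted
block); monotonicity is asserted up to two binomial standard errors of
Monte-Carlo noise, with power near 1 at ε = 0.2 and near α at ε = 0.

What passing these tests does **not** show about real data: multinomial
sampling has no overdispersion, no read-level error, no compositional
correlation beyond the tree, and the synthetic effect is a clean
single-split shift; real environmental differences smear across many
splits and depths.

## Problem sizes

Default-suite sizes were chosen to make every check sharp yet quick on a
single core: dense oracles up to n = 64 (200 trees), orthonormality to
n = 256, trend checks over n = 2⁶..2¹³ via the float recursion,
sparsity-growth means over 30 trees per size up to n = 4096, and the
calibration/power study at 500/200 replicates × 2000 resamples.  The full
suite runs in about a minute; `scripts/acceptance.py` in ~10 seconds.

## Known limitations

* Polytomies are handled by zero-length binarization (see above), not by
  the k-regular wavelet theory.
* The uniform ensemble is ordered-shape uniform; other "uniform tree"
  conventions (leaf-labelled, PDA) differ.
* Variance asymptotics inherit a float-cancellation loss of ~1–2 digits
  at n ~ 10⁴ (E(EPL)² ≫ Var); the exact rational path is available below
  the cap when full precision matters.
* `Var(EPL)`'s expansion converges slowly (relative error ~2% at
  n = 8192 is expected from the dropped O(n²) term); tests therefore
  assert trends for the variance, not pointwise agreement.
* No ordination, plotting, UniFrac/DPCoA, or kernel-learning layers; TSV,
  Matrix Market and Newick are the only interchange formats.
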