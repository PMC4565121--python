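# Methods

`mitoreticulum` models the mitochondrial reticulum (chondriome) of a
spherically symmetric animal cell as a dynamic graph whose fusion and
fission rates are shaped by the microtubule (MT) cytoskeleton.  Three model
layers feed into each other: a polymer model of the centrosome-organized MT
array, analytic densities of fiber contour and fiber crossings occupied by
mitochondria, and the fission/fusion graph dynamics solved both
deterministically (mass action) and stochastically (exact event-driven
simulation).

## Cell geometry and the microtubule array

The cell is a sphere of radius L = 16 um.  All n_f MTs are grafted at the
centrosome (origin) with orientations uniform on the sphere, have equal
contour length L and are modelled as zero-thickness curves: at an MT radius
of ~12.5 nm, steric fiber-fiber interactions are negligible compared with
the proximity threshold sigma = 0.2 um.  Chains are not confined by the
cell boundary: no reflection rule is imposed, and the rare contour beyond
r = L simply does not contribute to profiles inside the cell (for the
reference stiffness the fibers are nearly radial, so this is a sub-percent
effect).

Each MT is a freely rotating chain (FRC): N = L/a bonds of length
a = 0.02 um at a fixed bond angle theta to the previous bond, with torsion
uniform on [0, 2 pi).  The persistence length is L_p = 2a/theta^2; the
inverse relation sets theta for a requested stiffness.  The reference
stiffness L_p = 32 um gives theta = 0.035355 rad.  One master seed spawns
an independent substream per chain (graft direction plus torsions), so
enlarging n_f extends an array without reshuffling existing chains.

Crossings are detected in two distinct senses:

* **Discrete crossing spots** (`detect_crossings`): contiguous runs of
  segment pairs with exact minimum distance < sigma are merged into one
  crossing at the minimum-distance point.  A KD-tree on bond midpoints
  prunes candidates; the output is identical to the all-pairs scan (tested).
  Every fiber pair also "crosses" at the grafting point itself; consumers
  interested in bulk crossings should drop r < 4 sigma.
* **Crossing-mass density** (`proximity_pair_density`): the double contour
  integral, over ordered pairs of distinct fibers, of the indicator that
  two axis points lie within sigma.  The discrete estimator weights every
  sub-sigma bond-midpoint pair by a^2 and bins it at the radius of each
  member.  This is the quantity the analytic S_00 describes (it carries
  units of contour^2 per radius) and is the one used for
  theory-vs-simulation validation; the discrete spot count differs from it
  by a geometry-dependent factor ~ pi (sigma^2 - d^2)/sin(phi) per spot and
  is reported for inspection, not for the quantitative comparison.

## Occupancy of the fibers

Motor-driven transport along an MT is described at steady state by a
drift-diffusion balance, psi eps - d eps/d rho = 0, where
0 <= eps(rho) <= 1 is the fraction of fiber contour at position rho covered
by mitochondria and psi (1/um) is the drift-to-diffusion ratio.  On the
accessible interval [l1, l2] this gives eps = C e^(psi rho) with C fixed by
n_f * int eps = M; psi = 0 gives the uniform profile
eps = M/(n_f (l2 - l1)) = 0.34483 at the reference values.

When the normalisation would push eps above 1 (this happens already at the
reference cell for psi = -0.2, where the unconstrained profile reaches
1.06 at l1), `occupancy` returns the capacity-limited steady state: eps
saturates at 1 on a contiguous interval at the crowded end and decays
exponentially away from the break point rho*, which is fixed by mass
conservation.  This keeps 0 <= eps <= 1 and conserves M exactly, which a
hard error or silent clipping would not.  A configuration whose mass cannot
fit at all (M > n_f (l2 - l1)) raises `OverloadedCytoskeletonError`.
The sign convention: psi > 0 biases mitochondria outward (toward MT plus
ends), psi < 0 toward the centrosome; psi is treated as carrying units of
1/um, so psi = +-0.2 tilts the occupancy by a factor e^(0.2 (l2-l1)) ~ 18
across the cell (or less, when saturation caps it).

## End-to-end distance distribution

The radial densities require P(r, rho), the probability density of the
distance r between the centrosome and the contour point rho of a
semiflexible fiber (graft orientation averaged over the sphere, so only the
scalar distance matters).  P depends on (x, kappa) only, with x = r/rho and
kappa = L_p/rho.

Two evaluation paths are implemented:

* **Theta-series pair** (`method="series"`): the stiff-limit density
  f(y), y = kappa (1 - x), as an oscillating exponential series, and its
  Jacobi-theta dual (a Hermite-type expansion) used near full extension.
  The branch split sits at y = 0.3, which coincides with the classical
  near-extension rule r > 0.9 rho at kappa ~ 3 and remains convergent for
  all kappa (an x-based split mis-selects the slowly converging dual for
  very stiff chains).  The closed-form normalisation uses
  int_0^Y f dy = 1/2 - g(Y) with g the alternating theta sum (Poisson-dual
  form below y = 0.15).  The series is an O(1/kappa) approximation: its
  shape error is ~5% of the peak at kappa = 3 and ~2% at kappa = 8.
* **Spectral table** (`method="spectral"`): the exact distribution,
  obtained by propagating the characteristic function of the end-to-end
  vector in the Legendre basis of the tangent direction
  (d a_l/ds = -[l(l+1)/(2 kappa)] a_l + i q (c_l a_{l+1} + c_{l-1} a_{l-1}),
  phi(q) = a_0(1)) and inverting with the exact sine-series sampling
  theorem: q phi(q) is the sine transform of p(x)/x, which is supported on
  [0, 1], so p(x) = 2x sum_k (k pi) phi(k pi) sin(k pi x).  Rows are
  tabulated on a universal grid of 36 log-spaced kappa in [0.15, 8] times
  1601 x values and interpolated bilinearly (linear in log kappa).  The
  table is built lazily once per process (~30 s) and validated against
  150 000-chain FRC histograms to within sampling error (|z| <= 3) across
  the full kappa range.

The default (`method="auto"`) uses the spectral table for kappa <= 8 and
the series beyond, where its error is at the few-0.1% level after the
contour integration.  The net evaluation accuracy of the tabulated P is a
few tenths of a percent; comparisons against Monte Carlo therefore carry a
0.5% relative accuracy floor in addition to the sampling error.

## Radial densities

With j mitochondria superimposed at a fiber point (steric constraints limit
j < 3),

    Q_j(r) = n_f int_r^L P(r, rho) eps(rho)^j d rho,

in um of contour per um of radius; Q_0 is the bare cytoskeleton.  The
integration is restricted to rho >= r (contour closer to the graft cannot
reach the shell), split at the occupancy kinks l1, l2, and the segment
starting at rho = r uses Gauss-Legendre nodes clustered toward r by a
quartic map: for stiff fibers the integrand is a near-diagonal ridge of
width ~ r^2/(2 L_p) that a uniform rule never resolves.  Conservation
int Q_1 dr = M holds to < 0.03% for psi in [-0.2, 0.2].

The density of two-fiber crossings occupied on both fibers is

    S_jj(r) = Q_j(r) int Q_j(xi) A(xi, r) / (4 pi xi^2) d xi,

where A(xi, r) = 2 pi xi [xi - (xi^2 - sigma^2 + r^2)/(2r)] is the area of
the radius-xi sphere inside a sigma-ball at radius r, clamped to
[0, 4 pi xi^2] (the clamp covers the near-centrosome case where the whole
sphere lies inside the ball); the integral runs over
[max(r - sigma, 0), min(r + sigma, L)].  Where Q_j is locally constant this
reduces to the bulk asymptotic S_jj ~ sigma^3 Q_j^2/(3 r^2), accurate to
~1% away from the centrosome and from the outer shell r > L - 5 sigma
(where Q_0 collapses within the ball and the premise fails).  `CellDensities`
tabulates all profiles on a dense internal grid once per configuration.

## Rate fields and the deterministic steady state

Node densities per shell (in graph edges per um of radius; the edge length
is 0.2 um) obey mass-action balances

    u2 = (alpha_1 / 2) u1^2,  u3 = alpha_2 u1 u2,  u1 + 2 u2 + 3 u3 = 2 Q1,

with tip-to-tip fusion of two free ends making a bulk node (ratio alpha_1 =
k+/k-) and tip-to-side fusion of a free end with a bulk node making a
three-way branch (alpha_2 = l+/l-).  Substitution gives a strictly
increasing cubic in u1, so the non-negative root is unique; it is bracketed
on [0, 2 Q1] and solved by Brent's method (residual < 1e-8 Q1; verified
against long-time ODE integration of the full rate system to 1e-6).
Shells are independent: there is no radial transport of graph nodes at
steady state.

The position dependence enters through the rate fields

    alpha_1(r) = c1 gamma (Q2 + S11) / qbar^2,
    alpha_2(r) = c2 gamma S11 / qbar^2,

where gamma is the global fusion-to-fission propensity of the enzymatic
machinery, the numerators are the densities of fusion-competent
configurations for each reaction (superimposed same-fiber pairs plus
occupied crossings for sequential fusion; occupied crossings alone for
branching), and qbar = M/(edge_length * L) is the cell-mean edge density.
Two design choices deserve comment:

* **Fixed intensive divisor.**  Dividing by the local Q1(r)^2 instead of
  qbar^2 would cancel the occupancy dependence of S11 ~ Q1^2 exactly,
  leaving alpha_2 a pure geometric 1/r^2.  Under that choice a drift of
  psi = +-0.2 (occupancy tilt ~5x) can never overcome the (12/4)^2 = 9x
  radial decay of the crossings, and the drift-induced reversal of the
  clustering pattern -- a central behaviour of the model -- is impossible.
  The fixed divisor preserves the quadratic feedback of fiber occupancy
  into the branching rate.  The local form remains available as
  `rate_field(..., normalization="local")`.
* **Calibration of c1, c2.**  The two dimensionless amplitudes set where on
  the gamma axis the interesting regime sits; they are fixed once against
  the model's operating anchors -- mean segment length s(gamma) peaking at
  gamma ~ 0.1 at mid-cell with a peak of ~3 um, perinuclear s(gamma = 0.1)
  not significantly below 1 um, peripheral segments of a few um -- giving
  c1 = 8000, c2 = 155 (gamma_max(8 um) = 0.100, s_peak = 3.0 um).  With the
  quadratic mass-action closure s grows like sqrt(gamma) below the peak, so
  these anchors imply that deep fragmentation (u1 ~ 2 Q1) is reached only
  for gamma below ~1e-3; at gamma = 0.01 the reference cell is already
  moderately fused, though its cluster-size distribution is still
  exponential (branching is negligible there).  One cannot have both the
  few-um peak at gamma ~ 0.1 and near-total fragmentation at gamma = 0.01
  under any constant rescaling of these forms.

Derived structure: the mean segment length s(r) = 2 Q1/(u1 + 3 u3) (in
edges; times 0.2 um) counts linear stretches between degree-1/3 nodes, and
the partition border is the smallest radius at which bulk nodes outnumber
branching nodes while branching dominates further in.  With the frozen
calibration the branching-dominated core exists for gamma >~ 0.3 and its
border moves outward with gamma (0.88, 1.36, 2.0 um at gamma = 0.3, 1, 3).

## Stochastic graph simulation

The agent-based model evolves an explicit set of fixed-length edges whose
endpoints are grouped into nodes of degree 1-3, under four channels:
tip-to-tip fusion (propensity (k+/Omega) u1(u1-1)/2), bulk fission
(k- u2), tip-to-side fusion ((l+/Omega) u1 u2) and branch fission (l- u3,
detaching one uniformly chosen incident branch -- the exact microscopic
reverse of tip-to-side fusion).  Timescale: k- = l- = 1; only the ratios
alpha shape the stationary structure.  The volume factor is Omega = dr:
with node counts N_i = u_i dr in a shell of width dr, the stationary
relations reproduce the deterministic per-shell equations (the
deterministic-stochastic consistency test is the binding contract for this
choice).

Fusing the two ends of one edge onto each other -- directly or through a
bulk node -- would create a loop below graph resolution and is excluded;
cycles of two or more edges are allowed.  Excluded picks are realised as
exact null events (time advances, the state does not), which yields
per-pair rates on allowed transitions only; free-end pairs are drawn
uniformly among *distinct* pairs.  Both details are load-bearing: an
exhaustive continuous-time Markov chain oracle on 3- and 4-edge systems
(all reachable labelled endpoint partitions, dense stationary solve)
detects either mistake at chi-squared p ~ 0.  Stationary samples for that
comparison are taken at fixed simulated time, not after a fixed number of
events: the post-event state follows the jump chain, which oversamples
high-propensity states.

Equilibration: burn-in of 20 events per edge, then windows of 10 events
per edge until the mean free-end counts of two consecutive windows agree
within 1.96 combined standard errors (4 batch means per window), capped at
8 windows.  Ensembles use counter-based per-run substreams spawned from a
master seed.  Shell edge counts are allocated from Q1(r) dr by
largest-remainder rounding, so the total is exactly M/edge_length = 5000
edges (1 mm) and remains so through any event sequence.

## Problem sizes and what the tests show

Default validation scales are chosen to keep the full suite in a few
minutes: the theory-vs-Monte-Carlo density comparison uses 100 fibers and
16 seeds per persistence length (per-fiber-normalised quantities are
n_f-independent in expectation; fewer seeds simply widen the 3-SE band),
the deterministic-stochastic comparison 40 runs at 5000 edges, and the
cluster-phenomenology ensembles 30-40 runs per shell, versus 300 fibers /
100 seeds / 1000 runs for publication-quality figures.  The S_00 comparison
is restricted to shells with at least 100 pooled raw pairs -- beyond
r ~ 12 um the pair counts are dominated by rare near-parallel fiber pairs
and per-seed counts are far from normal -- and to r in [4 sigma, 0.95 L].

The synthetic cytoskeleton is the model's own study system, not a stand-in
for imaging data: passing tests show the implementation reproduces the
model's internal mathematics (polymer statistics, density integrals, mass
action, Markov dynamics) and its qualitative cell-biological signatures,
not that any particular real cell follows it.  Real MT arrays are dynamic,
not all grafted at one centrosome, and mitochondria exchange between
fibers; none of that is represented.

## Known limitations

* Crossings of three or more fibers are neglected (they fall off much
  faster with r and matter only at the immediate centrosome vicinity).
* The exact published forms of the position-dependent rate prefactors are
  not available; the implemented fields reproduce the documented radial
  shapes and operating regime but the amplitudes c1, c2 are a calibration,
  not a derivation.  Quantities tied to absolute gamma values other than
  the anchors should be read qualitatively.
* Shells are uncoupled: mitochondria do not migrate between shells during
  graph evolution, and edges are indivisible units of 0.2 um.
* The stiff-series evaluation path is kept for transparency but is only an
  O(1/kappa) approximation; the spectral table covers kappa <= 8 and is
  the accuracy reference.
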