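# Methods

## The measurement model

A reporter operon carries RFP, an intrinsic (Rho-independent) terminator,
and GFP under one promoter. The fraction of RNAP molecules terminating at
the terminator (termination efficiency, TE) is read out from the deficit in
downstream (GFP) expression relative to upstream (RFP) expression, each
normalized to a terminator-free reference construct:

    TE = 1 − (P_GFP / P_GFP,ref) / (P_RFP / P_RFP,ref)

During balanced exponential growth the per-cell synthesis rate of a
fluorescent protein is

    P = μ f (1 + μτ / ln 2),

where μ is the growth rate (min⁻¹, from the slope of ln OD₆₀₀ vs time),
f = ∂F/∂OD is the fluorescence-per-biomass slope, and τ is the fluorophore
maturation half-time (min). The bracket corrects for the invisible pool of
not-yet-matured protein: with maturation rate ln2/τ and dilution rate μ,
the mature fraction at steady state is 1/(1 + μτ/ln2), so the observed
slope underestimates synthesis by exactly that factor. Because TE is a
double ratio against the reference, it is insensitive to fluorometer gain
and to τ itself as long as the same τ is applied to construct and
reference; τ defaults (GFP 15 min, RFP 40 min) are typical literature
values for fast-folding GFPs and slower RFPs and are configurable
everywhere. For constructs whose RFP gene was modified (different 3′ end or
no translation), the GFP-only form TE = 1 − P_GFP/P_GFP,ref is used
instead; it equals the dual form whenever RFP expression matches the
reference.

Window selection: μ and f are estimated on the longest contiguous run of
points with OD ∈ [0.02, 0.3] whose ln(OD) regression reaches R² ≥ 0.99
(ends trimmed if needed); all bounds are user-overridable. One μ per
culture is shared by both channels. Replicates are quantified
independently and aggregated as mean ± standard error. Negative TEs under
noise are reported, not clipped, so that downstream fitting sees the true
error structure.

## The coupling model

In bacteria the pioneer ribosome trails RNAP on the nascent transcript. A
terminator hairpin can only fold if, at the moment RNAP reaches the
termination site, the ribosome sits more than α nt (here α = 27) behind the
first base of the hairpin stem; a closer ribosome sequesters stem sequence
and forces readthrough. Both machines move stochastically, so the
ribosome–hairpin distance X at that moment is random; modelling it as
Poisson with mean λ = d + c (d the stop-codon-to-hairpin spacer length, c a
sequence-specific offset) gives

    TE(d) = TE₀ [1 − CDF(α, λ(d))],

with TE₀ the terminator's maximal efficiency (0.9 for the tR2 terminator
used as the reference parameterization; offsets c = 15 for the W-series and
c = 7 for the R-series of constructs). Because the source prose is
ambiguous about repression exactly at X = α, both threshold conventions are
supported (`inclusive`: repression iff X ≤ α, the default; `strict`:
X ≤ α − 1); every headline number holds under either.

Fitting. The model is linear in TE₀ given (α, c…), so fitting is an
exhaustive integer grid search over α ∈ [0, 60] and per-series
c ∈ [−10, 40] with the closed-form conditional least-squares solution
TE₀ = Σwᵢteᵢmᵢ / Σwᵢmᵢ², mᵢ = 1 − CDF(K, dᵢ+cᵢ), clamped to [0, 1].
The grid keeps the optimum global and deterministic; ties break toward the
smallest α, then the smallest offsets. Grid points where any dᵢ + c < 0 are
rejected (a negative Poisson mean is meaningless), not clamped. TE₀ is
shared across series by default. Weights (e.g. 1/SE²) are optional;
the default is unweighted, matching how such TE–distance curves are
usually fit. Uncertainty comes from a case-resampling bootstrap over
constructs with percentile intervals.

Identifiability note: (α, c) enter only through CDF(α, d+c), which is
nearly invariant under the joint shift (α−k, c−k); with realistic noise
(σ = 0.02, 3 replicates) the recovered α and offsets occasionally move one
step — rarely two — along this ridge, while TE₀ is pinned to within
~0.005. This is inherent to the model, not to the optimizer.

## The mechanistic simulator

A continuous-time Markov (Gillespie) simulation of one RNAP and the first
translating ribosome grounds the Poisson approximation. RNAP steps 1 nt at
rate k_rnap (default 30 nt/s); the ribosome steps one codon (3 nt) at rate
k_ribosome (default 15 codons/s — free translocation is intrinsically
faster than transcription, so the pioneer ribosome catches up and then
trails RNAP); initiation fires at rate k_init (default 1/1.5 s⁻¹,
reflecting a 1–2 s initiation time) once the RBS region is clear of RNAP
and a ribosome placement respects steric exclusion. Exclusion: the A site
plus 10 nt of downstream protection may never enter the ~12 nt of mRNA
RNAP sequesters (4–5 nt protected plus 7–8 nt in the DNA:RNA hybrid). The
ribosome halts with its A site on the stop codon. When RNAP reaches the
decision point (hairpin + U-tract end), X = hairpin_start − A-site is
recorded and termination is drawn Bernoulli(TE₀) if the ribosome is beyond
the threshold, else Bernoulli(readthrough_floor, default 0). Hairpin
folding kinetics are deliberately abstracted into (TE₀, α).

Choices that were genuinely open:

* Time model: exponential waiting times with single-nt RNAP and
  single-codon ribosome steps; no kinetic scheme was prescribed.
* Only the pioneer ribosome is simulated; trailing ribosomes do not affect
  the first-ribosome–RNAP distance that sets repression.
* X is measured from the A site; the threshold α absorbs the offset to any
  other reference point (footprint edge), so the two conventions are
  jointly calibrated rather than independently meaningful.
* Initiation gating: a ribosome is placed only when both the RBS is clear
  and placement satisfies exclusion. Consequently the expected head start
  of RNAP over a newly initiated ribosome is
  max(r_p, s − r + d_p + r_p) + k_rnap/k_init nt (r_p RNAP protection, d_p
  ribosome downstream protection, s − r start-codon-to-RBS-end distance):
  ≈ 72 nt at defaults, consistent with RNAP being a few tens of nt away
  when translation starts.
* Catch-up is recorded as the first steric block at least one ribosome
  footprint past the start codon; contact during the placement transient is
  not catch-up. At default rates the pioneer ribosome catches up within
  ~100–200 nt; a ribosome slower than RNAP essentially never does (<1%
  boundary fluctuations).
* Default ORF length is 225 codons (RFP-like). This matters: the coupled
  regime the Poisson model describes requires the ribosome to have caught
  up before the terminator, which needs a few hundred nt of coding
  sequence. Short ORFs put the system in an initiation-dominated regime
  where TE(d) is no longer monotone.
* Per-position rate maps exist for both machines. A transcriptional pause
  lets the ribosome close the gap; a translational pause lets RNAP escape
  and partially restores termination for in-ORF terminators — the
  direction the in-ORF measurements show.
* Reproducibility: trajectory i uses an independent substream seeded by a
  counter derived from the config seed, so runs are bit-for-bit identical
  and order-independent.

The Poisson-adequacy diagnostic fits a plain Poisson by method of moments
to the finite X samples and reports a pooled-bin χ² (expected ≥ 5 per bin,
one dof charged for the mean) plus the mean/variance ratio. It is a
diagnostic, not an assertion: the simulated X has a structural lower bound
at the stop codon and need not be exactly Poisson — which is precisely the
approximation the closed-form model makes.

## Synthetic data

The generators define the test conditions; they are first-class, tested
code. Construct panels span the measured spacer ranges (W: 8–48 nt,
R: 9–59 nt) with one terminator-free reference and optional uncoupled
(-30U style) variants whose ground-truth TE is TE₀ (no ribosome ever
loads, so repression is abolished). Growth curves sample OD every 30 min
from OD 0.002 at μ = 0.02 min⁻¹ (doubling ≈ 35 min); fluorescence is the
balanced-growth steady state of the two-pool maturation model, so F is
exactly linear in OD and the quantifier's correction inverts the
generator exactly — the noiseless round trip is exact by construction,
which is what makes it a meaningful consistency check of both codes.
Measurement noise is multiplicative lognormal on OD and fluorescence
(scale-proportional instrument noise); TE tables get additive Gaussian
noise (σ default 0.02, matching the visual scatter of replicate TE error
bars; the underlying replicate scatter was never tabulated, so this is a
calibration choice). What the generators do not emulate: lag and
stationary phase, plate-position and evaporation effects, plasmid
copy-number variation, mRNA-stability differences. Tests passing on these
fixtures therefore validate the computational pipeline, not the
instrument model.

## Spacer design

Spacers are rejection-sampled uniform random DNA screened for GC fraction
(≤ 0.5), maximal G/C run (≤ 3), and complementary k-mers (k = 6) against
the terminator hairpin arms and the spacer itself. The k-mer screen is a
deliberate proxy for secondary-structure prediction: the design criteria
are qualitative (low GC, no structure competing with hairpin folding), and
a thermodynamic folder can be plugged in behind the same report
interface. K-mers with fewer than two G/C bases are exempt from the
self-complementarity screen — a pure A/T duplex is far too weak to compete
with a GC-rich terminator stem. An SD-like motif followed by a start codon
at 4–12 nt spacing triggers a warning (potential internal initiation
site), never a rejection.

## Problem sizes and numerics

Defaults throughout are the sizes used by the test-suite and the
acceptance script: TE tables at unit-spaced distances with 3 replicates
(285 points) fit in ~0.2 s; simulator properties use 10⁴ trajectories per
condition (binomial SE ≈ 0.003–0.005 on TE); bootstrap defaults to
B = 500 resamples. Poisson CDFs are evaluated through the regularized
incomplete gamma function (exact to machine precision; verified against
direct pmf summation to 1e-12 up to λ = 100). Degenerate inputs are
explicit errors, not silent fixes: non-positive OD, constant-OD windows,
negative Poisson means, all-censored distance samples.

## Known limitations

* The coupling model's offsets c are purely phenomenological; nothing maps
  sequence to c (the observed W/R difference is attributed to
  sequence-specific elongation dynamics that are not modelled).
* Termination is a single Bernoulli at the decision point; hairpin folding
  kinetics, RNAP backtracking, U-tract composition and Rho-dependent
  termination are out of scope.
* The simulator models one ribosome; polysome effects and trans-translation
  of non-stop mRNAs are not represented.
* TE quantification assumes mRNA stability is unchanged across constructs;
  where the real assay cross-checked this at the mRNA level, the package
  has no counterpart.
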