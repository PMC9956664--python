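# Methods

## The optical model

All computations live in the paraxial regime. The pseudophakic eye is a
chain of refracting surfaces — spectacle plane, cornea (thin or thick),
thin IOL, retina — connected by homogeneous media. A formula prediction
is obtained by transforming vergences backwards from the retina: with
lengths in metres and the aqueous/vitreous index n = 1.336,

```
z   = n/(AL − ELP)              vergence leaving the IOL plane
V   = z − PIOL                  vergence entering the IOL
Vc  = n/(ELP + n/V) − Dc        vergence in air before the (thin) cornea
SEQ = Vc/(1 + VD·Vc)            refraction at the spectacle plane
```

where `Dc = (nK − 1)/R` is the thin-lens corneal power and VD the
spectacle vertex distance. The thick-cornea variant replaces the single
surface by corneal back surface → stroma (thickness CCT, index nC) →
front surface, each step a subtraction of surface power or a reduced
translation. Both chains agree with an independently coded 2×2
ABCD-matrix raytracer to better than 1e−9 dpt (enforced in the tests),
which is the strongest internal-consistency check available without
clinical data.

Every formula is the composition `ELP part → vergence part`:

| formula    | ELP part (published form)                               | vergence part                                             |
|------------|---------------------------------------------------------|-----------------------------------------------------------|
| Hoffer Q   | pACD + AL/tangent expression, AL clamped to [18.5, 31] mm, K from Rpow at nK = 1.3375 | thin chain at ELP + 0.05 mm, Dc from Rpow |
| Holladay 1 | corneal-height ACD (R floored at 7 mm, corneal width 12.5·AL/23.45 capped at 13.5 mm) + SF | thin chain over AL + 0.2 mm, Dc from Rmean |
| Haigis     | a0 + a1·ACD + a2·AL                                      | thin chain, Dc from Rmean                                  |
| Castrop    | ACD + C·LT + H                                           | thick chain over the Cooke sum-of-segments length 1.23853 + 0.95855·AL − 0.05467·LT, back radius 0.834·Rmean, + offset R |

Index variation is restricted to the vergence part: the ELP expressions
always use the published index, so perturbing the main-part index
leaves every ELP bit-identical (a tested invariant). Hoffer Q's 0.05 mm
retinal offset is treated as vergence-part geometry because it enters
the vergence equation, not the ELP regression. Hoffer Q's tangent
arguments are interpreted in degrees, the convention of the common
published implementations. Two radius summaries are used: the
arithmetic mean Rmean = (R1+R2)/2 and the power-mean radius
Rpow = 2·R1·R2/(R1+R2), whose thin-lens power equals the mean
meridional power for any index; Hoffer Q consumes Rpow, the other
formulas Rmean.

The corneal module exposes the three thick-lens powers. With reduced
thickness t = CCT/nC and surface powers P1, P2:
`Pequiv = P1 + P2 − t·P1·P2`, `Pbvp = Pequiv/(1 − t·P1)`,
`Pfvp = Pequiv/(1 − t·P2)`. Back-vertex power is the emergent vergence
for parallel light from air; front-vertex power is defined as the
emergent vergence of the reversed system. Under this standard
definition the reference cornea (7.7/6.8 mm, 500 µm) matches the Javal
keratometric power at nC ≈ 1.3247; a front-vertex figure of 1.3210 is
sometimes quoted for this configuration but is not reproduced by the
standard definition, and the convention behind it is unclear — the
package documents the discrepancy rather than guessing an alternative
definition. Index solving uses bisection on nC ∈ [1.30, 1.42] to 1e−12
(the selected power is monotone in nC there).

## Constant optimisation

The merit is the sum of squared prediction errors, minimised by a
damped Gauss–Newton (Levenberg–Marquardt) iteration written out in
`iolopt.optimize`: Marquardt-scaled damping `(JᵀJ + λ·diag(JᵀJ))`,
forward-difference Jacobians, λ divided by 10 on accepted steps and
multiplied by 10 otherwise. Stopping criteria: 1000 iterations
maximum, accepted merit improvement below 1e−16, or step norm below
1e−14. Keeping the loop explicit (rather than calling a canned
least-squares driver) makes the accepted-merit sequence — which is
monotone by construction and asserted in the tests — and the
iteration/function-evaluation counts available as first-class
diagnostics, and lets degenerate eyes be penalised deliberately: any
eye whose vergence chain hits a near-zero denominator at the current
parameters contributes a finite 100 dpt penalty residual instead of a
NaN.

Free parameters are rescaled before damping (constants by 1,
the index by 0.01) because the index moves the merit roughly two
orders of magnitude faster per unit than the millimetre-scale
constants. Initialisation is staged: situation A starts from nominal
constants after a coarse ±4 mm grid scan of the additive position
constant (pACD/SF/a0/H); B and C start from A's optimum with the
published index; D warm-starts from the transferred index and, in
cross-validation, the source cohort's constants. On smooth synthetic
problems the warm start and a cold start reach the same optimum; the
staging simply reproduces fast convergence (tens of iterations).

Situation C appends a single residual `λ·√N·slope` to the PE vector,
where `slope` is the OLS slope of PE over Rpow (Hoffer Q) or Rmean
(others) in dpt/mm. How the two objectives should be weighted is
genuinely open; the package's choice is λ = 100·√N by default,
large enough that the trend term dominates once the PE residuals
plateau, which in practice nulls the slope to below 1e−6 dpt/mm while
changing the rms PE only in its last percent. λ is exposed everywhere
(`slope_weight` / `--lambda`), and λ → 0 recovers situation B (tested).
Fitting a mean-centred additive offset makes the post-fit mean PE
essentially zero: exactly for Castrop's refraction offset R, and to
within ±0.005 dpt for the ELP constants once the index is free
(situation B); with the index fixed (situation A) a structurally
mismatched cohort can retain a mean PE of a few hundredths of a
dioptre, the same pattern reported for clinical material.

The Haigis triplet is deliberately left unregularised despite the
collinearity of ACD and AL; the reported constants are therefore only
identifiable as a set, which is the behaviour of customary Haigis
optimisation.

## Synthetic cohorts

`iolopt.synthetic` draws biometry from a correlated Gaussian with the
marginal means/SDs of a typical European cataract population
(AL 24.10 ± 1.41 mm, CCT 559 ± 36 µm, ACD 3.19 ± 0.41 mm,
LT 4.62 ± 0.46 mm, R1 7.86 ± 0.28 mm, R2 7.67 ± 0.27 mm), rejecting
draws outside the marginal 95% spans widened by 20% of the span on each
side — soft tails without impossible eyes. The correlations
(AL–ACD 0.45, AL–LT −0.30, ACD–LT −0.35, R1–R2 0.95, AL–R1/R2 0.30,
others 0) are an assumption chosen as physiologically plausible and
verified positive-definite; only marginals are constrained by
published descriptive tables.

Outcomes come from a known forward model: a truth formula (default
Haigis with a0/a1/a2 = −0.6853/0.3417/0.2029 at nK = 1.3315) is
evaluated over the available IOL grid (6–30 dpt in 0.5 dpt steps), the
power closest to the −0.3 dpt target is implanted (ties towards the
lower power), and the achieved SEQ is the truth prediction plus
0.3 dpt Gaussian noise rounded to 1/8 dpt, recorded as sphere with
zero cylinder (the analysis consumes only SEQ, so astigmatism would
add no testable structure; VA is set to 1.0). With noise and rounding
disabled the chain closes exactly, which is what the recovery tests
exploit: situation A refits recover the generating constants to
machine precision, situation B recovers a perturbed generating index
to ±1e−4.

What passing these tests shows — and what it does not. Recovery on
synthetic cohorts validates the optical algebra, the split between ELP
and vergence parts, and the optimiser, because the data-generating
process is inside the model class. Real cohorts add IOL-design
aberrations, measurement-device biases, refraction subjectivity and
non-Gaussian tails; fitted constants and the size of the index's
benefit on real material will differ, and cross-formula structural
mismatch (e.g. the positive Holladay-1 radius trend that situation C
removes at some cost in rms PE) is emulated here by generating with
the thick-cornea model and fitting a thin-cornea formula.

## Numerical choices and degenerate inputs

* All internal optics in metres/dioptres; cohort I/O in mm/µm.
* Vertex distance defaults to 12 mm (configurable); descriptive tables
  of the source populations do not state it, and 12 mm is the
  convention of the Haigis formula literature.
* The Castrop offset R is additive to the predicted SEQ; only the
  fitted constant's sign depends on this convention, so any consistent
  choice is interoperable after optimisation.
* Vergence denominators within 1e−12 of zero raise a typed
  `DegenerateVergenceError` (scalar API) or yield NaN on request
  (vectorised optimiser path, which converts them to the 100 dpt
  penalty).
* Quantiles use Hazen plotting positions (k − 0.5)/n with linear
  interpolation; SDs use the n−1 denominator; the empirical CDF is
  right-continuous with fractions i/n.
* Cylinder sign dialect is accepted as-is (plus or minus): SEQ is
  invariant under cylinder transposition, so no conversion is applied.

Problem sizes in the test suite (cohorts of 150–800 eyes, 1000-eye
oracle sweeps, 2000-eye distribution checks) keep the full suite in the
seconds range while leaving every statistical check comfortably
powered.

## Known limitations

* Only the four disclosed formulas are implemented; undisclosed modern
  formulas cannot be optimised in this framework at all.
* No toric/astigmatic prediction and no post-refractive-surgery
  corneas: the keratometric radius-to-power conversion systematically
  fails there.
* Axial-length trend nulling is not implemented — only the corneal
  radius trend is an optimisation target.
* The ELP prediction parts are never re-estimated; varying the index
  inside the ELP regressions (where the corneal radius is itself a
  predictor, as in Hoffer Q and Holladay 1) might change results and is
  out of scope.
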