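# Methods

This note records the models implemented in looplab, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a user or maintainer would otherwise have to
reverse-engineer from the code.

## Signal model and state assignment

The analysis treats contact quenching as all-or-none: a frame is *closed*
(non-fluorescent, I = 0) when the minimum distance between the two reporter
groups is at or below a cutoff, *open* (I = 1) otherwise.  Distances equal
to the cutoff count as closed; the choice is measure-zero on continuous
data but is pinned so that reruns are bit-identical.  The two cutoffs used
for the peptide systems are exposed as constants: 0.45 nm for the
dye-labelled reporter pair (dye ring / Trp ring minimum distance) and
0.58 nm for the unlabelled pair (Trp rings plus C-terminal carboxylate vs
the N-terminal amino group).  The exact atom list "rings and the C-terminal
group" is not fully enumerable from the source material; the presets take
all ring heavy atoms plus the terminal carboxylate atoms and document
themselves in the `GroupSpec.name`.  Minimum distances ignore periodic
images: inputs must be whole molecules (pre-imaged if they came from a
periodic box); box handling belongs to the MD engine, not this package.

Cutoffs can also be auto-selected: build the probability-density free
energy profile F(r) = -kB T ln p(r) along the end-to-end minimum distance
and take the position of the barrier for escaping the global short-distance
minimum.

## Correlation functions

`fluorescence_autocorrelation` computes G(tau) = <I(t)I(t+tau)> / <I>^2
over all complete (t, t+tau) pairs inside the finite record (no periodic
wrap).  This normalisation makes G decay to 1, which the two-state fit
family `1 + amplitude * exp` requires; a mean-subtracted (covariance)
variant is available behind the `normalization` flag for users who prefer
curves that decay to 0.  The default lag grid is logarithmic, about 30
points per decade from dt to a tenth of the record, because the processes
of interest span picoseconds to hundreds of nanoseconds and uniform grids
waste almost all their points in one decade.  Off-grid lags snap down to
the dt grid with a warning.

The hydrogen-bond existence autocorrelation C(t) is the probability that a
bond intact at a start time is intact a time t later.  The default
*intermittent* convention tolerates transient breaking (the convention
under which nanosecond bond lifetimes are usually quoted); a *continuous*
mode requiring the bond to stay intact throughout is provided for
sensitivity analysis and is non-increasing by construction.  Both
correlators are exact: unit tests pin them to an O(N*L) brute-force double
loop at 1e-12 on random binary inputs.

## Kinetic fits

**Two-state.** G(tau) = 1 + (1/K) exp(-tau/tau_r), least squares over a
caller-set window (default 6-300 ns, the experimentally resolvable range
for nanosecond FCS).  K = [open]/[closed] is the adopted convention: it is
the one that makes the printed closing/opening times internally consistent
with ~30-40% open populations; the reciprocal convention is a config
switch.  From (K, tau_r): tau_c = tau_r (1+K), tau_o = tau_r (1+K)/K,
fraction_open = K/(1+K); the algebra round-trips to 1e-12 and satisfies
1/tau_r = 1/tau_c + 1/tau_o to 1e-9 by construction.  A fitted amplitude
statistically indistinguishable from zero raises a no-relaxation error —
the physically meaningful "no detectable process slower than the time
resolution" outcome, not a failure.

**Multi-exponential.** Beyond a 3 ps window start, curves are fitted with
baseline + A1 exp[-(t/tau1)^beta] + sum Ai exp(-t/tau_i), one or two
exponentials; `auto` selects 1 vs 2 by small-sample corrected AIC with
equal per-point weights (the source analysis chose by chain length, which
is not a reusable rule).  The stretched-exponential objective is
multimodal, so fits multistart from log-spaced tau guesses with beta
starting at 0.7.  Fits with correlation coefficient <= 0.95 are flagged,
not rejected: desk-scale synthetic curves may legitimately sit below the
gate that microsecond trajectories clear.  Relative amplitudes are
percentages of G(0) - 1.

**Hydrogen-bond lifetime.** C(t) is fitted with baseline + stretched ps
component + one ns exponential; the ns relaxation time is the reported
lifetime.  The stretched term with beta near 1 and the exponential form a
degenerate family, so components whose amplitude confidence interval spans
zero are dropped and the dominant exponential-like component supplies the
lifetime.  For a Markov on/off bond the analytic form is
C(t) = p + (1-p) exp(-(k_break+k_reform) t), p = k_reform/(k_break+k_reform),
which the fit recovers within 10% on sampled fixtures.

**Power law.** gamma is the OLS slope of ln k on ln n (optionally
1/sigma^2-weighted when rate errors are supplied; the unweighted fit is the
default and reproduces the printed exponent -1.4 from the packaged
experimental closing times of the five longest labelled peptides).  The
fit is scale-equivariant: rescaling all rates changes the prefactor only.

**Errors.** Where a record can be split, one-sigma errors are the n = 2
sample standard deviation |a - b| / sqrt(2) of the two half-record results.

## Free-energy profiles

F(r) = -kB T ln p(r) from a plain histogram (default bin width 0.02 nm, a
choice of this package; the source states none), minimum shifted to zero,
empty bins masked and never imputed.  No Jacobian r^2 correction is applied
by default — the profile is over the probability density of the scalar
distance — with a flag for the corrected variant.  kB = 0.0083145
kJ/mol/K; default temperature 293 K.

Barrier detection works on a 3-bin moving-average smoothed profile with
ties broken toward smaller r, restricted to bins holding at least 5
samples, and requires the barrier to be *prominent*: both heights must
exceed 3 Poisson standard errors of the corresponding F differences.
Without the prominence requirement, histogram-tail noise manufactures
barriers in single-well profiles and the no-barrier contract could never
hold on sampled data.  Because the minimum of a flat-bottomed profile
wanders under Poisson noise, `minimum_location` refines the arg-min by a
local quadratic fit (+-0.25 nm) and is accurate to ~1% at 1e6 samples
where the raw arg-min errs by ~5%.

## Synthetic generators

**Telegraph.**  Exact exponential dwell times are drawn per state and only
then discretised onto the dt grid.  Per-step Bernoulli flipping was
rejected because it biases dwell statistics whenever a dwell constant
approaches dt, which is exactly the picosecond regime the multi-exponential
analysis targets.  A zero rate yields an absorbing state.  Initial state:
open, closed, or a stationary draw.

**Hydrogen-bond on/off series.**  Independent telegraphs per bond (1 =
intact) with rates k_break, k_reform; each bond gets its own child stream
of the master seed, so bonds are independent and individually
reproducible.

**Bead-spring chain.**  One bead per residue, harmonic bonds of rest
length b = 0.38 nm (the C-alpha virtual-bond spacing), optional
harmonic-cosine bending, optional WCA excluded volume, and an optional
smooth short-range attraction U = -eps (1 - (r/r_a)^2)^2 between beads at
least three apart in sequence — the minimal, non-directional surrogate for
intra-backbone hydrogen bonding; eps = 0 is the "no hydrogen bonds"
analog.  Dynamics are overdamped Euler-Maruyama steps in an ensemble
advanced by one numba-compiled kernel; a master seed fixes both the
equilibrium initial draw and the noise stream, so runs are reproducible
and parameter pairs sharing a seed are closely paired.  Units are nm, ps,
kJ/mol with kB = 0.0083145 kJ/mol/K; `friction` is the drag coefficient
zeta in amu/ps (1 amu nm^2/ps^2 = 1 kJ/mol closes the unit system), and
the bead diffusion constant is kB T / zeta.

Defaults (all artifact choices, echoed into generator metadata): bond
stiffness 2000 kJ/mol/nm^2 keeps bond-length fluctuations at sigma = 0.035
nm, so the 1.5 b connectivity bound sits 5.4 sigma away while the stable
Euler step dt ~ 0.1 zeta/k stays affordable; dt = 5e-5 ps; friction 1
amu/ps; attraction range 0.5 nm; WCA sigma 0.3 nm.  Tests that need tighter
equilibrium statistics (the freely-jointed <R^2> check) stiffen the bonds
to 8000 kJ/mol/nm^2 and shrink dt accordingly, trading steps for bias: the
exact radial average <l^2> of a harmonic bond exceeds b^2 by ~5 kBT/(k b^2),
about 1% at that stiffness.

**Closure rates.**  For scaling studies the closure rate is 1/mean
first-passage time from equilibrium open configurations (end separation
above the capture radius) to first contact, with a capture radius of
0.2 nm — deliberately small against the coil size of every chain length
studied.  This choice matters, and the estimator sensitivity is worth
recording.  The Gaussian-chain scaling theories (contact-probability-
controlled at the shallow end, diffusion-controlled at the steep end,
exponents -1.5 to -2.1) are derived in the point-capture limit a << R.
At a = 0.45 nm — the peptide-signal cutoff, comparable to the 1 nm coil
of the 8-bead chain — the measured first-passage slope over N = 8-24
steepens to about -2.13, past the diffusion-controlled edge, purely from
finite-size corrections; at a = 0.2 nm it measures about -1.79, inside
the band, consistent with theory.  Conversely, rates read off a binarised
equilibrium record (1/mean open dwell, with or without a two-cutoff
hysteresis) are equilibrium-flux estimators: recrossing-dominated, they
track the contact probability and measure about -1.48 to -1.50 regardless
of recording details.  The first-passage definition at small capture
radius is therefore the one that measures the quantity the theories
describe.  Phantom chains start from exact Gaussian-equilibrium draws, so
no equilibration is spent; interacting chains accept an equilibration
stretch.  Closed replicas freeze, so the kernel's cost tracks the mean
first-passage time rather than the slowest straggler.

**Ideal geometries.**  Backbones (N, H, CA, C, O; no side chains) are
grown by the natural-extension-reference-frame construction with standard
bond lengths/angles and trans peptide links; amide H sits 1.0 A from N,
anti to the preceding C=O — the same reconstruction applied to united-atom
inputs before Kabsch-Sander evaluation, whose N-terminal residue carries
no H.  The hairpin builder uses an ideal type-I' two-residue turn and
strand dihedrals (-140, 150), slightly flattened relative to textbook
antiparallel values so that the two arms stay in register and the
Kabsch-Sander criterion sees a ladder of at least two rungs at every size;
with textbook (-139, 135) the accumulated strand twist breaks the register
after the first rung.  A self-intersection check (non-bonded heavy atoms
closer than 0.15 nm) rejects impossible dihedral requests.

### What the generators do not emulate

No solvent, no electrostatics, no atomistic force field, no dye
photophysics beyond binary contact quenching, no detector shot noise or
diffusion term in G(tau).  Passing tests therefore demonstrate that the
*analysis chain* is correct and unbiased on data with the assumed
statistical structure (two-state switching, Markov bond kinetics, Rouse-like
chain dynamics); they do not validate force fields or absolute nanosecond
time constants, which require microsecond atomistic simulation and are out
of scope.

## Structure analysis

Two hydrogen-bond criteria: geometric (N...O <= 0.35 nm and N-H to N-O
angle <= 30 deg, a common trajectory-analysis default, used for plain bond
counting) and the Kabsch-Sander electrostatic energy
E = 0.084 * 332 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol with a bond
below -0.5 kcal/mol (the DSSP default).  The two disagree at the margins
by design — the energy criterion has no hard distance gate and accepts
well-aligned bonds slightly beyond 0.35 nm — so reports always label which
criterion produced them.  Donors and acceptors must be >= 2 residues apart;
pairs >= 3 apart count as inter-strand candidates.

Beta-segments are ladders of >= 2 consecutive inter-strand bonds with a
uniform register shift (antiparallel or parallel) — the operational
definition used here instead of full DSSP bridge/ladder bookkeeping, whose
8-state assignment is not needed for two-to-six-bond segments.
Ramachandran statistics exclude glycine and use +-30 deg rectangles around
the beta (-135, 135) and PPII (-75, 140) centres; the sources give centres
only, so the half-width is a documented choice.

## Pipeline

A YAML run config with explicit unit suffixes (_nm, _ns, _K) names exactly
one input source (trajectory, distance CSV, or generator block), the
cutoff policy, windows and a master seed; every stage seed derives from
it.  Reports echo the config and its hash, so identical config + seed
reproduce identical numbers on one platform.  Stage starts, ends and all
quality-gate flags are logged; any stage failure aborts with the stage
named and earlier outputs preserved.

## Problem sizes in the shipped checks

The acceptance script and end-to-end tests use 1 ms telegraph records at
dt = 0.1 ns (1e7 samples), 1e6 draws for free-energy oracles, 40-bond
Markov matrices of 4e5 frames, and chain ensembles of 48-384 replicas
(first-passage runs weight the end lengths, which carry most of the
scaling slope's leverage), sizes at which every asserted tolerance is
several standard errors wide on one core in minutes.  Larger records
tighten the recoveries but change no conclusion.

## Known limitations

Single-curve fits only (no global multi-curve fitting, no Bayesian
posteriors); no enhanced-sampling reweighting of profiles; XTC/DCD binary
trajectory formats are out of the core (PDB/XYZ only); the chain simulator
is a statistical surrogate whose absolute times are not comparable to
molecular dynamics; the beta-ladder logic does not classify helices or
full DSSP states.
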