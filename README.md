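# looplab

Loop-closure kinetics of unfolded polypeptide chains: a tested, reusable
analysis pipeline for extracting closing/opening time constants, their
chain-length scaling, hydrogen-bond lifetimes and free-energy profiles from
fluorescence-like binary signals and molecular trajectories — together with
synthetic generators that reproduce the statistical structure of such data,
so every stage is testable at desk scale.

## Who this is for

End-to-end contact formation between the termini of an unfolded peptide is
one of the earliest events in protein folding.  Experimentally it is probed
by contact quenching: a dye at one end is quenched on van der Waals contact
with a tryptophan at the other, switching fluorescence off (closed state)
and on (open state), and fluorescence correlation spectroscopy (FCS) turns
the fluctuating signal into kinetics.  Computationally, the same analysis
is applied to distance time series from molecular simulation.  looplab
implements that shared analysis chain for anyone studying loop-closure or
two-state contact kinetics in disordered chains.

## The model

The second-order autocorrelation of the binary fluorescence signal I(t) is

    G(tau) = <I(t) I(t+tau)> / <I>^2 .

Assuming an all-or-none transition between the fluorescent (open) and
quenched (closed) states,

    G(tau) = 1 + (1/K) exp(-tau / tau_r),

with K = [open]/[closed] the equilibrium constant and tau_r the relaxation
time.  Mean closing and opening times follow as

    tau_c = tau_r (1 + K),    tau_o = tau_r (1 + K) / K,

so 1/tau_r = 1/tau_c + 1/tau_o and fraction_open = K/(1+K).  Closure rates
k = 1/tau_c of random-coil chains scale with the number of peptide bonds n
as k ~ n^gamma, gamma between -1.5 and -2.1 for Gaussian chains.  Faster,
sub-nanosecond relaxations are modelled by a stretched exponential plus one
or two exponentials; hydrogen-bond kinetics by the existence
autocorrelation C(t) (probability that a bond intact at time 0 is intact at
time t); and the open/closed cutoff by the barrier of the free-energy
profile F(r) = -kB T ln p(r) along the end-to-end minimum distance.

## Worked example

Generate a two-state (telegraph) signal with closing time 20.5 ns and
opening time 48.5 ns — the experimental constants of the 10-peptide-bond
GS repeat — and recover them through the full pipeline:

```python
import looplab

p = looplab.TelegraphParams(k_close=1/20.5, k_open=1/48.5,
                            dt=0.1, n_steps=10_000_000, seed=1)
signal = looplab.gen_telegraph(p)
curve = looplab.fluorescence_autocorrelation(signal, max_lag=300.0)
fit = looplab.fit_two_state(curve, window=(6.0, 300.0))
print(f"tau_c = {fit.tau_c:.1f} ns, tau_o = {fit.tau_o:.1f} ns, "
      f"open fraction = {fit.fraction_open:.2f}")
```

prints (seed 1):

```
tau_c = 20.3 ns, tau_o = 48.1 ns, open fraction = 0.30
```

i.e. the fit recovers the generator truth (20.5 / 48.5 ns) within about one
percent on a 1 ms record, and the ~30% open population typical of these
peptides.  Fitting the packaged experimental closing times of the five
longest labelled peptides gives the scaling exponent:

```python
from looplab.kinetics_fitting import experimental_closing_rates, fit_powerlaw
fit = fit_powerlaw(experimental_closing_rates(n_min=10), n_min=10)
print(round(fit.exponent, 1))   # -1.4
```

The same operations are available from the shell:

```bash
looplab generate --kind telegraph --seed 1 \
    --params '{"k_close":0.0488,"k_open":0.0206,"dt":0.1,"n_steps":1000000}' \
    --out states.csv
looplab correlate --states states.csv --max-lag 300 --out g.csv
looplab fit two-state --curve g.csv --window 6:300 --out fit.json
```

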