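# mabsolkit

Analysis toolkit for the solution behaviour of antibody fragments (Fab/Fc-like
ellipsoidal ~50 kDa proteins) in electrolyte: protein size and shape metrics,
hydration-shell and ionic double-layer profiles, umbrella-sampling free-energy
reconstruction, second osmotic virial coefficients, and the matching
experiment-side scattering estimators. It is aimed at people who analyse
protein–protein interaction data from molecular simulation or from
small-angle scattering / static light scattering, and who want every stage
testable against synthetic inputs with known ground truth.

## What it computes

- **Size/shape** — radius of gyration Rg² = Σmᵢ(rᵢ−R)²/M and its probability
  distribution; anatomical long-axis/width/height dimensions as projections of
  marker-residue pair vectors onto the gyration-tensor principal axes;
  Shrake–Rupley solvent-accessible surface area.
- **Hydration & double layer** — unnormalised surface-minimum-distance RDFs
  (counts per bin width; the integral to r equals the mean count within r),
  linear-fit rescaling, coordination numbers, residence (survival)
  probabilities, the net-charge profile Qnet(r) = Q_protein + n₊(r) − n₋(r),
  its exponential screening-length fit A₀e^(−r/ζ), and the Poisson–Boltzmann
  Debye length ζ = (εk_BT / 2e²N_A·10³C)^{1/2}.
- **Free energies & virials** — WHAM reconstruction of the potential of mean
  force ΔG(r) from harmonic umbrella windows, and
  B22 = −(2πN_A/Mw²)∫(e^{−ΔG/RT} − 1)r²dr with declared core/tail rules.
- **Scattering** — self-consistent Guinier fits (ln I = ln I₀ − q²Rg²/3 over
  q·Rg ≤ 1.3) and SLS Debye-plot regression (intercept 1/Mw, slope 2·B22).
- **Synthetic data** — generators for every input above with known ground
  truth: a breathing bead ellipsoid, exponentially screened ion clouds,
  Boltzmann-sampled umbrella windows from analytic PMFs, and noisy
  Guinier/Debye-plot curves.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Reconstruct a PMF from synthetic umbrella windows and convert it to B22:

```python
import mabsolkit as mk

# ground truth: 14 kJ/mol Gaussian well at 3.6 nm; 51 windows, k = 1000
pmf_spec = mk.AnalyticPMFSpec(form="gaussian_well", well_depth=14.0,
                              well_center=3.6, well_width=0.25)
protocol = mk.UmbrellaProtocol(samples_per_window=50_000, seed=42)
windows = mk.gen_umbrella_windows(pmf_spec, protocol)

profile = mk.wham(windows, n_bins=200)
print(f"well depth: {profile.delta_g.min():.2f} kJ/mol")

result = mk.pmf_to_b22(profile, mw=49635.0)
print(f"B22 = {result.b22:.3e} mol mL/g^2")
```

Output:

```
well depth: -13.84 kJ/mol
B22 = -1.448e-03 mol mL/g^2
```

The reconstructed well depth is within the statistical error of the
generating 14 kJ/mol well, and the negative B22 reflects the net attraction;
a purely repulsive profile gives B22 > 0. The same pipeline is available from
the shell:

```bash
mabsolkit simulate umbrella --depth 14 --samples 5000 --seed 42 --out-dir win/
mabsolkit wham --manifest win/windows.json --out pmf.csv
mabsolkit b22 --manifest win/windows.json --mw 49635
mabsolkit pb-zeta --epsr 78 --conc 0.15 --temp 300   # -> 0.79 nm
```

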