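# gkvisc

Green–Kubo shear viscosity estimation from equilibrium pressure-tensor
fluctuations, with a time-decomposition fitting protocol, bootstrap
convergence diagnostics, a synthetic validation generator with analytically
known viscosity, and a companion rheometry module for protein-solution
concentration–viscosity analysis.

## Who this is for

Simulators who record the pressure tensor of an equilibrium MD run (e.g. a
concentrated protein solution in an NVT ensemble) and want a defensible
zero-shear viscosity with an uncertainty, and experimentalists who want to
fit and invert cone–plate rheometry data for the same systems.

## The method

The shear viscosity follows from the Green–Kubo relation

    η = V / (k_B T) ∫₀^∞ ⟨P_αβ(t₀) P_αβ(t₀+t)⟩ dt₀-avg dt

where `P_αβ` are off-diagonal pressure-tensor elements, `V` the box volume
and `T` the temperature. Six statistically exploitable channels are used per
trajectory: `P_xy`, `P_xz`, `P_yz` (each averaged with its transpose) and
the diagonal differences `(P_xx−P_yy)/2`, `(P_xx−P_zz)/2`, `(P_yy−P_zz)/2`.
For a nanoscale system the running integral η(t) is noise-dominated at long
lag, so the asymptote is extracted with a two-stage *time-decomposition*
fit over an ensemble of N independent trajectories:

1. the inter-trajectory standard deviation σ(t) of the running integrals is
   fitted with a power law `A·t^b` (log–log linear regression);
2. the ensemble mean ⟨η(t)⟩ is fitted, with weights `t^(−b)`, by the
   saturating triexponential

       η(t) = B·[α τ₁(1−e^(−t/τ₁)) + β τ₂(1−e^(−t/τ₂)) + (1−α−β) τ₃(1−e^(−t/τ₃))]

   whose analytic long-time limit `η_∞ = B(α τ₁ + β τ₂ + (1−α−β) τ₃)` is the
   viscosity estimate. Repeat-set estimates are aggregated with a
   conservative root-sum-of-squared-deviations spread.

Validation uses ensembles of summed Ornstein–Uhlenbeck modes, whose ACF
`Σ cᵢ e^(−t/τᵢ)` makes the target viscosity `V/(k_B T)·Σ cᵢτᵢ` exact.

The rheometry module converts cone–plate torque to viscosity
(`η = 3Mα / (2πR³ω)`) and fits the Ross–Minton law
`η(ρ) = η₀·exp([η]ρ / (1 − (k/v)[η]ρ))` to (concentration, viscosity)
tables, with curve inversion and a concentration-uncertainty band. A
measured monoclonal-antibody table at 297 K ships with the package.

## Worked example

```python
import gkvisc as gv

# synthetic ensemble with exactly known viscosity
spec = gv.OuSpec(modes=[(0.5, 1.0), (0.05, 50.0)], time_step=0.1,
                 n_steps=200_000, volume=100.0, temperature=298.0, seed=7)
print(gv.analytic_viscosity(spec))      # 0.0007291581056416028 mPa·s

ens = gv.synthetic_running_curves(spec, 12, sets=3, max_lag=2000.0)
plaw, fit, est = gv.fit_ensemble(ens, seed=0)
print(plaw.b)                           # 0.6987821973333773
print(fit.eta_infinity)                 # 0.0008090531562196197 mPa·s
print(est.set_etas)                     # [0.000978..., 0.000859..., 0.000667...]
```

The noise exponent b ≈ 0.70 says σ(t) grows sub-diffusively; the fitted
asymptote 8.1·10⁻⁴ mPa·s sits 11 % above the analytic 7.3·10⁻⁴ mPa·s, inside
the spread of the three 4-trajectory set estimates — at this small ensemble
size the estimate is noise-limited, and grows ~3× more accurate at the
63-trajectory scale the test suite exercises.

```python
# rheometry: fit the bundled mAb table and invert at a target viscosity
data = gv.load_mab_dataset()
fit = gv.ross_minton_fit(data)
print(fit.eta0)                          # 1.2237623499765675 mPa·s
print(fit.intrinsic_viscosity)           # 0.008203739770058519 mL/mg
print(gv.invert_concentration(fit, 9.2)) # 162.03589882249796 mg/mL
```

i.e. a solution measuring 9.2 mPa·s corresponds to ≈162 mg/mL on the fitted
concentration–viscosity curve.

From the shell the same pipelines are available as `gkvisc visc`,
`gkvisc acf`, `gkvisc bootstrap`, `gkvisc synth` and `gkvisc rheo`
(see `gkvisc --help`); options come from flags or a `--config` YAML file.

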