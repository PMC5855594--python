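# glycobind

Binding-kinetics analysis for galectin-3 / neo-glycoprotein
interactions: forward simulation and global fitting of surface plasmon
resonance (SPR) sensorgrams, ELISA dose-response fitting with
multivalency metrics, and linear interaction energy (LIE) free-energy
estimation — with a seeded synthetic-data generator standing in for
instrument output.

## Who this is for

Glycobiologists and biophysicists characterizing lectin–glycoconjugate
binding: galectin-3 (Gal-3) is a β-galactoside-binding lectin and cancer
marker, and multivalent neo-glycoproteins (BSA decorated with m copies
of a poly-LacNAc-type glycan) are among its strongest known ligands,
with picomolar dissociation constants. The package turns raw titration
data — or synthetic stand-ins with known ground truth — into rate
constants, affinities, and potency metrics with propagated errors.

## The models

SPR reports a response R(t) in RU during an analyte injection
(association) and buffer wash (dissociation). Four kinetic schemes are
supported: the 1:1 Langmuir model

    A + L ⇌ AL,    dR/dt = ka·C·(Rmax − R) − kd·R,    KD = kd/ka,

the heterogeneous-ligand model (two independent site classes, response =
sum of two 1:1 terms), a bivalent-analyte model, and a
heterogeneous-analyte (competing species) model. Rate constants are
fitted **globally** across all concentrations of a titration, in log
space with seeded multistart, and candidate models are ranked by AICc.
ELISA curves are fitted as one-site saturation (apparent Kd) or
four-parameter logistic inhibition (IC50); multivalency is quantified by
the relative potency rp = IC50(glycan)/IC50(neo-glycoprotein) and by
rp/m, the cluster-glycoside-effect per glycan. LIE computes
ΔG = α·Δ⟨V_LJ⟩ + β·Δ⟨V_el⟩ from mean interaction energies
(α = 0.181, β = 0.3 by default). Details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a five-point titration of the strongest ligand regime
(ka = 5.9×10⁶ M⁻¹s⁻¹, kd = 8.5×10⁻⁵ s⁻¹, i.e. KD = 14.4 pM) with noise,
drift, and a bulk offset; double-reference it; refit globally:

```python
import glycobind as gb

params = gb.KineticParams(gb.ModelKind.LANGMUIR_1TO1, 5.9e6, 8.5e-5, 100.0)
sched = gb.PhaseSchedule(t_assoc=120.0, t_dissoc=600.0, dt=0.5)
concs = gb.serial_dilution(250e-12, 2.0, 5)       # 250 pM, two-fold, 5 steps

channels = gb.generate_sensorgram_series(
    params, concs, sched,
    gb.NoiseSpec(sd=0.5, drift=0.01, bulk=5.0, seed=7),
)
series = gb.double_reference_series(channels.active, channels.interspot,
                                    channels.blank)
result = gb.global_fit(series, gb.ModelKind.LANGMUIR_1TO1,
                       gb.FitOptions(n_starts=2, seed=0))
print(f"ka = {result.params.ka1:.3g} +/- {result.stderr['ka1']:.2g} M^-1 s^-1")
print(f"kd = {result.params.kd1:.3g} +/- {result.stderr['kd1']:.2g} s^-1")
print(f"KD = {result.kd_eq1.value:.3g} +/- {result.kd_eq1.stderr:.2g} M")
```

Output:

```
ka = 5.71e+06 +/- 3.4e+05 M^-1 s^-1
kd = 9.49e-05 +/- 7.1e-06 s^-1
KD = 1.66e-11 +/- 1.6e-12 M
```

The generating values lie within roughly one standard error: the
fitter recovers a 16.6 pM affinity from a 14.4 pM ground truth under
0.5 RU noise after double referencing.

The same pipeline is available from the shell:

```sh
glycobind fixtures --out fixtures.csv        # reported ligand-series values
glycobind potency --fixtures fixtures.csv --out potency.csv
glycobind simulate --config run.yaml --out series.csv --seed 1
glycobind fit --input series.csv --kind langmuir_1to1 --out report.json
glycobind compare-models --input series.csv --out selection.json
glycobind elisa-fit --input curve.csv --mode inhibition --out ic50.json
glycobind lie --vdw-bound -150 --vdw-free -50 --elec-bound -80 --elec-free -30
```

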