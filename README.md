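# thermogate

Heat-activation threshold analysis for thermosensitive ion channels.

Thermo-TRP channels such as TRPV1 open steeply with temperature, and the
temperature at which a channel begins to conduct — its activation
threshold — is the quantity that distinguishes, say, a cool-adapted
amphibian ortholog (~28–34 °C) from the rat channel (~43 °C). `thermogate`
implements the standard electrophysiology analysis chain for assigning such
thresholds from heat-ramp recordings, together with the companion assays
usually reported alongside them:

* **Arrhenius threshold detection** — the current magnitude at the holding
  potential is plotted as ln |I| against 1/T (T absolute); the threshold is
  the temperature at the intersection of linear fits to the shallow
  (leak-dominated) baseline and to the steepest component of the profile.
* **Q10** — from the steep-segment slope, Ea = −slope·R and
  Q10 = exp(Ea·10 / (R·T_ref·(T_ref+10))).
* **Half-maximal activation temperature** — where the leak-subtracted
  current reaches 50 % of its ramp maximum.
* **Capsaicin-standardized current** — |I| at a probe temperature divided
  by the same cell's saturating capsaicin response.
* **Hill dose–response fits** for capsaicin (µM) and protons (pH), with
  EC50 / pH50 and Hill coefficient.
* **Thermal-shift (DSF) melt curves** — ΔF(t)/ΔF_max = (F(t) − F(20 °C)) /
  (F_max − F(20 °C)) normalization and Boltzmann-fit T_m.
* **Stability/threshold correlation** — Pearson r (exact-t p, Fisher-z CI)
  between mutational folding-energy changes ΔΔG and thresholds, plus the
  usual group statistics (Student's t, one-way ANOVA, Dunnett /
  Tukey–Kramer post-hocs).

Because raw recordings of this kind are rarely published, the package
ships a thermodynamic synthetic-data generator: a two-state van't Hoff
gate P(T) = 1/(1 + exp((ΔH − TΔS)/(RT))) over a Q10 ≈ 1.3 leak, plus
Hill, unfolding and mutant-panel generators — so every stage of the
analysis is verifiable by parameter recovery against known ground truth.

## Worked example

```python
import thermogate as tg

# a channel with half-maximal activation at 36 °C, 3 % recording noise
params = tg.GatingModelParams.from_t_half(36.0, noise_sd=0.03, seed=7)
trace = tg.simulate_heat_ramp(params)            # 10→40 °C at 0.5 °C/s
result = tg.analyze_trace(trace)

print(f"threshold        {result.threshold_C:.2f} C")
print(f"Q10              {result.q10:.1f}")
print(f"half-max T       {result.t_half_act_C:.2f} C")
print(f"I(40C)/I_caps    {result.i_at_probe_norm:.3f}")
```

```
threshold        26.69 C
Q10              9.2
half-max T       34.95 C
I(40C)/I_caps    0.834
```

The detected threshold (26.7 °C) marks the onset of activation — where the
gated current emerges from the leak — and therefore sits well below the
generating half-activation temperature (36 °C), which the half-max summary
recovers (34.95 °C, within the ramp's grid). Q10 ≈ 9 reflects the steep
Arrhenius slope of the gated current diluted by leak within the fitted
window; the current at 40 °C is 83 % of the cell's capsaicin response.

The same analyses run from the shell on tidy CSV inputs:

```sh
thermogate simulate ramp --config ramp.json --seed 1 --out data/
thermogate analyze-ramp data/traces.csv --ref data/capsaicin_refs.json --out results/
thermogate analyze-dose doses.csv --out results/
thermogate analyze-melt plate.csv --method boltzmann_fit --out results/
thermogate correlate panel.tsv --out results/
thermogate run --config pipeline.json --out results/   # full pipeline + report
```

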