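"""Quality-filter a raw CE-MS peak list and deconvolute charge states.

Signals must be multiply charged (z > 1), reach S/N >= 4 and appear in at
least 3 consecutive spectra; surviving signals are grouped across charge
states into neutral monoisotopic masses.
"""

from cemspipe import SyntheticConfig, deconvolute, filter_signals, simulate_study

study = simulate_study(SyntheticConfig(n_patients=1, seed=4))
signals = study.samples["P001"]

kept = filter_signals(signals)
features = deconvolute(kept, mass_tol_ppm=25, time_tol_min=0.1)

print(f"raw signals:        {len(signals)}")
print(f"after filters:      {len(kept)}  (z>1, S/N>=4, >=3 spectra)")
print(f"peptide features:   {len(features)}  (charge series collapsed)")
f = max(features, key=lambda f: f.intensity)
print(f"strongest feature:  {f.mass:.3f} Da at {f.time:.2f} min, "
      f"intensity {f.intensity:.3g}, charges {sorted(f.source_charges)}")
total_in = sum(s.intensity for s in kept)
total_out = sum(f.intensity for f in features)
print(f"intensity conserved: {total_in:.6g} -> {total_out:.6g}")
# Each feature is one peptide: its neutral mass is the intensity-weighted
# mean over its charge states and its intensity their sum.
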