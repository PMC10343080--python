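"""Simulate a small labelled cohort of FTIR mixture spectra.

Builds 300 synthetic drug samples (48.1 % fentanyl-positive), writes them as
JCAMP-DX files plus a labels table, and prints the class balance and the
share of positives that fall below the 5 % FTIR detection-limit analogue —
the samples a technician reading the spectrum would be expected to miss.
"""

from ftirnet import SimConfig, default_library, generate_dataset, write_dataset

cfg = SimConfig(n_samples=300, seed=7)
samples, table = generate_dataset(cfg, default_library())
write_dataset(samples, table, "scratch/example_cohort", cfg)

pos = table[table.strip_label == 1]
below = pos[pos.fentanyl_concentration_pct < 100 * cfg.ftir_lod]
print(f"samples: {len(table)}, strip-positive: {len(pos)} ({100*len(pos)/len(table):.1f}%)")
print(f"positives below the {100*cfg.ftir_lod:.0f}% FTIR limit analogue: "
      f"{len(below)} ({100*len(below)/len(pos):.1f}% of positives)")
print("wrote JCAMP-DX spectra + labels.csv to scratch/example_cohort/")
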