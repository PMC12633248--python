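"""Small two-group contrast: implant a bistability deficit and detect it.

Simulates 15 + 15 subjects with the alpha-band mode-separation knob lowered
in the second group, computes the metric table and runs the full
inferential stack (Welch, Cohen's d, BH-FDR, robust regression,
Freedman-Lane permutation) for the bistability index.
"""

from eegcrit import CohortSpec, band_contrasts, gen_cohort
from eegcrit.metrics import metric_table

spec = CohortSpec(n_hc=15, n_mdd=15, n_channels=2, fs=250.0,
                  effects={(4, "bis"): -1.5}, seed=4)
recordings, manifest = gen_cohort(spec)
table = metric_table(recordings)
res = band_contrasts(table, n_perm=500, rng=0, metrics=("bis",))
cols = ["band", "n_hc", "n_mdd", "d", "p", "q", "p_perm"]
print(res[cols].round(4).to_string(index=False))
# The implanted alpha cell (8.3-10.5 Hz) should show a clearly negative d
# (patients lower) with small p/q; the other twelve bands are null.
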