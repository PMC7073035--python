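"""Pathway expression along a bulk differentiation time course.

Simulates a neuronal-induction-style TPM time course where cells exit the
cell cycle at day 4, then summarizes log-transformed expression of each DSB
pathway and the G2/M program per time point with 95% confidence bands.
"""

from dsbscore import SimConfig, load_cell_cycle_sets, load_dsb_sets, simulate_bulk_timecourse
from dsbscore.bulk import log_tpm, timecourse_summary

table, _ = simulate_bulk_timecourse(SimConfig(seed=2), time_points=(0, 2, 4, 7, 14),
                                    replicates=3, cycle_off_day=4.0)
sets = load_dsb_sets("human") + [s for s in load_cell_cycle_sets("human")
                                 if s.name == "G2M"]
summ = timecourse_summary(log_tpm(table), sets)
wide = summ.pivot(index="day", columns="set", values="mean").round(2)
print(wide.to_string())

# G2/M expression collapses at the day-4 cycle exit and HDR follows it down,
# while NHEJ stays flat: the homology-dependent pathway tracks proliferation,
# the end-joining pathway does not.
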