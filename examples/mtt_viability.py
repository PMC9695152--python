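"""Reduce an MTT plate to percent viability relative to untreated cells.

Generates a synthetic plate emulating a melanoma-cell photothermal
experiment: cells treated with different nanoparticle samples, with and
without NIR irradiation, read at 570 nm against a 670 nm reference.
"""

import phototherm as pt

plate = pt.generate_mtt_plate(
    group_effects={          # true viability fractions, non-irradiated arms
        "untreated": 1.00,
        "AuNTs@690": 0.88,
        "AuNTs@780": 0.82,
        "AuNTs@890": 0.95,
    },
    irradiated_effects={     # after 15 min NIR laser exposure
        "untreated": 1.00,
        "AuNTs@690": 0.76,
        "AuNTs@780": 0.55,
        "AuNTs@890": 0.91,
    },
    replicates=3,
    noise_cv=0.04,
    seed=4,
)

table = pt.compute_viability(plate, control_group="untreated")
print(table.to_string(index=False, float_format=lambda v: f"{v:6.1f}"))
# viability_percent is each group's mean background-subtracted OD as a
# percentage of the untreated, non-irradiated control; sd_percent is the
# replicate spread on the same scale.  The strongest drop after irradiation
# marks the most phototoxic (best-converting) agent.
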