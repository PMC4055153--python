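"""Reduced-size study configurations shared by simulator and acceptance tests.

One geometry (10 sensors, 4 temporal per side, 250 Hz, 220 s -> 110 epochs,
90 analysed) is reused everywhere so the calibration curve cache is shared
across tests.
"""

import dataclasses

import alphavar as av

REDUCED = dict(
    n_per_group=21,
    n_sensors=10,
    n_temporal_per_side=4,
    sampling_rate=250.0,
    duration_s=220.0,
    epochs_analyzed=90,
)

#: Planted-effect condition for the power/recovery study (d ~ 1.2 by design).
EFFECT_CONFIG = av.CohortConfig(group_power_ratio=0.15, group_cv_delta=1.1, **REDUCED)

#: Recovery-study condition: the default planted group contrasts (the
#: duration-model recovery concerns the tinnitus group's CV-duration law and
#: needs no power-study-specific contrast).
RECOVERY_CONFIG = av.CohortConfig(**REDUCED)

#: Null condition: no group effect, flat duration relation.
NULL_REDUCED = dict(REDUCED, n_per_group=8)
NULL_CONFIG = av.CohortConfig(
    group_power_ratio=1.0,
    group_cv_delta=0.0,
    duration_model=(2.38, 0.0),
    **NULL_REDUCED,
)


def with_seed(config: av.CohortConfig, seed: int) -> av.CohortConfig:
    return dataclasses.replace(config, seed=seed)


def run_reduced(config: av.CohortConfig, seed: int) -> av.RunReport:
    cfg = with_seed(config, seed)
    return av.run_pipeline(av.RunConfig(cohort=cfg, target_rate=cfg.sampling_rate))
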