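"""Pre-built simulation scenarios.

The benchmark scenario emulates the design of the reference cohort in
:mod:`ctdna_horizon.datasets`: 26 cancer cases and 26 matched controls, of
which eight cases shed detectable ctDNA at the Early timepoint — seven via
driver-gene mutations inside the targeted panel (15 panel mutations in
total, 1-3 per participant, Early MAFs 0.33-26.3%) and one via aneuploidy
only. Very Early tumor fractions follow the reference fold-decreases (8.6
to 79-fold) where mutations remained detectable; participants whose Very
Early sample carried no detectable ctDNA use fold_decrease None, and one
participant's Very Early sample is unavailable. The scenario is an
emulation of the study design, not a fit to its data.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .simulate import ScenarioConfig, TumorProfile


def benchmark_shedders() -> tuple[TumorProfile, ...]:
    mk = TumorProfile.from_early_maf
    return (
        mk(0.0431, cancer_type="Rectal", stage="III", n_driver_mutations=2,
           fold_decrease=None, days_to_dx_early=96, days_to_dx_very_early=1208),
        TumorProfile(  # aneuploidy-only shedder: no in-panel driver mutations
            early_tumor_fraction=0.06, cancer_type="Liver",
            n_driver_mutations=0, aneuploid_fraction=0.30, fold_decrease=40.0,
            days_to_dx_early=84, days_to_dx_very_early=1230,
        ),
        mk(0.0033, cancer_type="Colon", stage="II", n_driver_mutations=3,
           fold_decrease=50.0, days_to_dx_early=104, days_to_dx_very_early=1270),
        mk(0.0337, cancer_type="Pancreatic", n_driver_mutations=1,
           fold_decrease=20.0, very_early_available=False, days_to_dx_early=20),
        mk(0.0250, cancer_type="Colon", n_driver_mutations=3,
           fold_decrease=50.0, days_to_dx_early=30, days_to_dx_very_early=1117),
        mk(0.2626, cancer_type="Lung", n_driver_mutations=2,
           fold_decrease=79.0, days_to_dx_early=112, days_to_dx_very_early=1197),
        mk(0.0139, cancer_type="Colon", stage="I", n_driver_mutations=2,
           fold_decrease=8.6, days_to_dx_early=12, days_to_dx_very_early=1117),
        mk(0.1340, cancer_type="Breast", n_driver_mutations=2,
           fold_decrease=None, days_to_dx_early=47, days_to_dx_very_early=1139),
    )


def benchmark_scenario(seed: int = 0) -> ScenarioConfig:
    """The default 26/26 case-control scenario with eight shedders."""
    return ScenarioConfig(
        n_cases=26, n_controls=26, seed=seed, shedders=benchmark_shedders()
    )


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
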