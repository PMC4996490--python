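"""End-to-end convenience pipelines built from the module primitives.

These wire the simulator through unit sampling, detection adjustment and
covariate summarisation into one modelling-ready bundle, mirroring how a
real survey analysis flows from raw observation records to a fitted RSF.
Primarily used by scripts and tests; each stage remains available
individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic
from .covariates import ModelSpec, summarize_units
from .detection import DetectionTable, accumulate_units
from .fit import ModelFit, fit_spec
from .units import assign_effort, assign_observations, sample_units


@dataclass
class StudyData:
    """One simulated survey, assembled for modelling."""

    landscape: synthetic.Landscape
    transects: pd.DataFrame
    observations: pd.DataFrame     # all detected groups
    truth: pd.DataFrame            # latent counts per segment-year
    flown_log: pd.DataFrame
    units: pd.DataFrame            # retained units with n_years
    obs_units: pd.DataFrame        # observations assigned to unit instances
    cov: pd.DataFrame              # unit covariate table
    counts: pd.DataFrame           # raw_sum / pseudocount / n_years per unit
    detection: DetectionTable
    true_model: synthetic.TrueModel
    design: synthetic.SurveyDesign

    @property
    def offset(self) -> np.ndarray:
        return np.log(self.counts["n_years"].to_numpy(dtype=float))


def simulate_study(seed: int,
                   config: synthetic.LandscapeConfig | None = None,
                   true_model: synthetic.TrueModel | None = None,
                   design: synthetic.SurveyDesign | None = None,
                   detection: DetectionTable | None = None,
                   n_points: int = 2000, min_years: int = 2) -> StudyData:
    """Simulate a complete survey and prepare the modelling tables.

    Defaults reproduce the study's conditions: ~17,000 km of systematic
    100-km transects at 60-km spacing over a ~1.6M km^2 landscape, 2,000
    with-replacement sample points, five survey years with ~4% dropout,
    and the published detection table.
    """
    if config is None:
        config = synthetic.study_landscape_config()
    if true_model is None:
        true_model = synthetic.study_true_model()
    if design is None:
        design = synthetic.SurveyDesign()
    if detection is None:
        detection = DetectionTable.standard()
    rng = np.random.default_rng(seed)
    s_land, s_tr, s_eag, s_units = rng.integers(0, 2**31 - 1, size=4)

    landscape = synthetic.generate_landscape(config, int(s_land))
    transects = synthetic.generate_transects(landscape, design, int(s_tr))
    observations, truth, flown_log = synthetic.simulate_eagles(
        transects, landscape, true_model, design, int(s_eag), detection=detection)
    units = sample_units(transects, n_points, int(s_units),
                         unit_length_km=design.unit_length_km,
                         unit_width_km=design.unit_width_km)
    units = assign_effort(units, flown_log, min_years=min_years)
    obs_units = assign_observations(observations, units)
    cov = summarize_units(units, landscape, half_width_km=design.unit_width_km / 2)
    counts = accumulate_units(obs_units, detection, units)
    return StudyData(landscape=landscape, transects=transects,
                     observations=observations, truth=truth, flown_log=flown_log,
                     units=units, obs_units=obs_units, cov=cov, counts=counts,
                     detection=detection, true_model=true_model, design=design)


def fit_study(data: StudyData, spec: ModelSpec, **kw) -> ModelFit:
    """Fit a model spec to an assembled study dataset."""
    return fit_spec(data.cov, data.counts["pseudocount"], data.offset, spec, **kw)
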