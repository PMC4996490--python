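"""Shared fixtures: small synthetic landscapes and surveys for fast tests."""

import numpy as np
import pandas as pd
import pytest

import eaglersf as e
from eaglersf.synthetic import CovariateSpec, LandscapeConfig, SurveyDesign, TrueModel


def small_config(extent=(400.0, 240.0), cell=2.0):
    """A small landscape exercising every covariate kind."""
    specs = {
        "elevation": CovariateSpec("continuous", mean=1800, sd=500, range_km=80, clip_min=0),
        "solar": CovariateSpec("continuous", mean=4000, sd=400, range_km=120, clip_min=0),
        "wind": CovariateSpec("continuous", mean=4, sd=1.2, range_km=100,
                              clip_min=1, clip_max=7),
        "forest": CovariateSpec("proportion", landscape_share=0.2, range_km=60),
        "developed": CovariateSpec("proportion", landscape_share=0.03, range_km=30),
        "road1_dist": CovariateSpec("distance", mean=25, sd=15, range_km=80, clip_min=0),
        "aspect": CovariateSpec("aspect", range_km=40),
    }
    return LandscapeConfig(extent=extent, cell_size_km=cell, covariate_specs=specs)


def std_config(extent=(1680.0, 960.0), cell=4.0, n_cov=4):
    """Standardised continuous covariates (mean 0, sd 1) for recovery tests."""
    ranges = [120, 80, 150, 60, 100]
    specs = {f"z{i+1}": CovariateSpec("continuous", mean=0.0, sd=1.0,
                                      range_km=ranges[i % len(ranges)])
             for i in range(n_cov)}
    return LandscapeConfig(extent=extent, cell_size_km=cell, covariate_specs=specs)


STD_BETA = {"const": -2.0, "z1": 0.9, "z2": -0.6, "z3": 0.3, "z4": -0.3}


def make_std_study(seed, n_points=2050, theta=1.5, extent=(1680.0, 960.0)):
    """Study-scale survey on standardised covariates with known coefficients."""
    return e.simulate_study(
        seed,
        config=std_config(extent=extent),
        true_model=TrueModel(beta=dict(STD_BETA), theta=theta),
        design=SurveyDesign(),
        n_points=n_points,
    )


@pytest.fixture(scope="session")
def detection_table():
    return e.DetectionTable.standard()


@pytest.fixture(scope="session")
def demo_study():
    """A mid-sized simulated survey shared across test modules (read-only)."""
    return e.simulate_study(
        seed=42,
        config=small_config(extent=(1200.0, 720.0), cell=4.0),
        true_model=TrueModel(
            beta={"const": -16.6, "elevation": 0.00187, "elevation^2": -3.1e-07,
                  "solar": 0.00589, "solar^2": -7.3e-07, "forest": -2.79,
                  "developed": -4.59, "wind": 0.274},
            theta=1.5),
        n_points=1000,
    )


@pytest.fixture(scope="session")
def demo_fit(demo_study):
    spec = e.ModelSpec(("elevation", "solar", "forest", "wind"))
    return e.fit_study(demo_study, spec)
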