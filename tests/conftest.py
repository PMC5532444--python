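import numpy as np
import pandas as pd
import pytest

from dyadsync.design import CouplingSpec, DropoutSpec, StudyDesign
from dyadsync.pipeline import analyze_study
from dyadsync.simulate import simulate_dyad, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """6-dyad study at the shortest inclusion-compatible duration."""
    design = StudyDesign(n_dyads=6, n_noise=3, conversation_duration_s=300.0, seed=101)
    return simulate_study(design, dropout=DropoutSpec(hazard_per_s=0.0))


@pytest.fixture(scope="session")
def small_study_analysis(small_study):
    """DRPs (real + 10 surrogates), CRQA params, cutoffs for the small study."""
    drps, params, cutoffs = analyze_study(small_study, surrogate_seed=77)
    return {"drps": drps, "params": params, "cutoffs": cutoffs}


@pytest.fixture(scope="session")
def coupled_dyad():
    """One dyad: in-phase affiliative + turn-taking argumentative, 300 s."""
    design = StudyDesign(conversation_duration_s=300.0, seed=5)
    rng = np.random.default_rng(202)
    return simulate_dyad(
        design, CouplingSpec(), "d01", "dual-task",
        ("affiliative", "argumentative"), rng,
    )


def make_drp_table(
    n_dyads=8,
    n_noise=4,
    lags=None,
    conv_effect=0.0,
    quad_effect=0.0,
    dyad_sd=0.0,
    conv_slope_sd=0.0,
    noise_sd=0.01,
    n_surrogates=0,
    data_quad_effect=0.0,
    seed=0,
):
    """Synthetic long-format DRP table with a known generative structure.

    rr = 0.05 + conv_effect*c + quad_effect*q + data_quad_effect*d*q
         + dyad intercept + dyad-specific conversation slope + noise.
    """
    rng = np.random.default_rng(seed)
    if lags is None:
        lags = np.arange(-50, 51)
    from dyadsync.gca import orthogonal_lag_polynomials

    _, q = orthogonal_lag_polynomials(lags)
    rows = []
    for i in range(n_dyads):
        dyad = f"d{i + 1:02d}"
        task = "noise" if i < n_noise else "dual-task"
        b_dyad = rng.normal(0, dyad_sd)
        b_slope = rng.normal(0, conv_slope_sd)
        for number, conv_type in enumerate(("affiliative", "argumentative"), start=1):
            c = 1.0 if conv_type == "argumentative" else 0.0
            sources = [("real", 0)] + [("surrogate", s + 1) for s in range(n_surrogates)]
            for source, sid in sources:
                d = 0.5 if source == "real" else -0.5
                rr = (
                    0.05
                    + (conv_effect + b_slope) * c
                    + quad_effect * q
                    + data_quad_effect * d * q
                    + b_dyad
                    + rng.normal(0, noise_sd, len(lags))
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "dyad": dyad, "conversation": number,
                            "conv_type": conv_type, "task": task,
                            "source": source, "surrogate_id": sid,
                            "lag": lags, "rr": rr,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
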