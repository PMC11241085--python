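import numpy as np
import pytest

import speechnorms as sn


@pytest.fixture(scope="session")
def group1():
    return sn.BUILTIN_SCHEMES["group1"]


@pytest.fixture(scope="session")
def normal_cohort():
    """642-participant cohort from the censored-normal family (the simulation
    method's own assumption), scores on the 4-point grid."""
    model = sn.default_model("R", "censored_normal")
    return sn.gen_cohort(642, model, seed=20240613)


@pytest.fixture(scope="session")
def skewed_cohort():
    """642-participant cohort from the left-skewed Beta family, emulating the
    ceiling-heavy score distributions of real clinic data."""
    model = sn.default_model("R", "skewed_beta")
    return sn.gen_cohort(642, model, seed=20240613)


@pytest.fixture(scope="session")
def smooth_normal_model():
    """Censored-normal model whose true mean follows the link-function form
    and whose SD grows linearly with PTA, so the true 5% quantile curve is
    smooth and representable by the fitted family — the pointwise oracle for
    curve-recovery tests.  PTA mixture weights follow the default scheme."""
    from speechnorms.synthetic import _CALIBRATION

    return sn.CohortModel(
        curve_pta=(0.0, 95.0),
        curve_sd=(5.5, 21.0),
        mean_params=sn.CurveParams(beta1=96.0, beta2=1e-4, beta3=1.9),
        pta_bins=tuple((r[0], r[1], float(r[2])) for r in _CALIBRATION["R"]),
        family="censored_normal",
        discretize=False,
    )


@pytest.fixture(scope="session")
def oncurve_records():
    """Noise-free records lying exactly on a known link curve."""
    true = sn.CurveParams(beta1=90.0, beta2=0.001, beta3=1.5)
    rng = np.random.default_rng(42)
    pta = rng.uniform(0.0, 90.0, 400)
    return true, [
        sn.EarRecord(f"P{i:03d}", "R", float(p), float(sn.eval_curve(true, p)))
        for i, p in enumerate(pta)
    ]


def make_cohort_csv(tmp_path, rows, header="participant_id,ear,pta,pbmax"):
    path = tmp_path / "cohort.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
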