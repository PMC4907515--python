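import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import metgain as mg
from metgain.datasets import example_trial_dataset, example_yield_means

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def yield_means() -> pd.DataFrame:
    """Bundled per-entry RF/RI mean yields (g/plot)."""
    return example_yield_means()


@pytest.fixture(scope="session")
def means_trial() -> mg.TrialDataset:
    """The same means re-encoded as a 32-plot dataset."""
    return example_trial_dataset()


def make_balanced_dataset(
    g=3, t=2, y=2, r=2, seed=0, integer=False, trait="yield"
) -> mg.TrialDataset:
    """Small balanced dataset with integer or float values."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in [f"e{i}" for i in range(g)]:
        for tr in ("RI", "RF")[:t]:
            for yy in range(1, y + 1):
                for rr in range(1, r + 1):
                    v = int(rng.integers(0, 30)) if integer else float(
                        rng.normal(500, 20)
                    )
                    rows.append(
                        dict(entry=e, treatment=tr, year=yy, rep=rr, **{trait: v})
                    )
    return mg.TrialDataset(pd.DataFrame(rows), [trait])


@pytest.fixture
def small_integer_ds() -> mg.TrialDataset:
    return make_balanced_dataset(g=3, t=2, y=2, r=2, seed=11, integer=True)


def make_blup_fixture() -> mg.TrialDataset:
    """Deterministic 12-progeny x 2-treatment x 2-year x 2-rep dataset.

    Generating truth: progeny SD 4, treatment shift +/-3, year shift +/-2,
    progeny-by-treatment and progeny-by-year SD 2, residual SD 5.
    """
    rng = np.random.default_rng(42)
    g = 12
    prog = [f"p{i:02d}" for i in range(g)]
    eff = dict(zip(prog, rng.normal(0, 4, g)))
    te = {"RI": 3.0, "RF": -3.0}
    ye = {1: 2.0, 2: -2.0}
    gt = {(p, tr): rng.normal(0, 2) for p in prog for tr in te}
    gy = {(p, yy): rng.normal(0, 2) for p in prog for yy in ye}
    rows = []
    for pp in prog:
        for tr in te:
            for yy in ye:
                for rl in (1, 2):
                    rows.append(
                        dict(
                            entry=pp,
                            treatment=tr,
                            year=yy,
                            rep=rl,
                            yld=500
                            + eff[pp]
                            + te[tr]
                            + ye[yy]
                            + gt[(pp, tr)]
                            + gy[(pp, yy)]
                            + rng.normal(0, 5),
                        )
                    )
    return mg.TrialDataset(pd.DataFrame(rows), ["yld"])


@pytest.fixture(scope="session")
def blup_ds() -> mg.TrialDataset:
    return make_blup_fixture()
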