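import numpy as np
import pandas as pd
import pytest

from spawntrack import synth, telemetry


@pytest.fixture(scope="session")
def deployments():
    return synth.default_deployments()


@pytest.fixture(scope="session")
def zone_map(deployments):
    return telemetry.ZoneMap.from_deployments(deployments,
                                              synth.default_zone_polygons())


@pytest.fixture(scope="session")
def control_tags():
    return synth.default_control_tags()


@pytest.fixture(scope="session")
def small_tags():
    return synth.make_tags(n_fish=8, seed=5)


@pytest.fixture(scope="session")
def small_sim(deployments, small_tags, control_tags):
    """One compact telemetry simulation shared by read-only tests."""
    truth = synth.TelemetryTruth()
    return synth.simulate_telemetry(truth, deployments, small_tags, control_tags,
                                    ("2007-06-04", "2007-07-20"), seed=11)


def random_detections(n=500, n_tags=6, seed=0, deployments=None):
    """Unstructured detection table for filter/partition oracles."""
    rng = np.random.default_rng(seed)
    recs = (deployments["receiver_id"].to_numpy() if deployments is not None
            else np.arange(1, 43))
    t0 = pd.Timestamp("2007-06-01")
    ts = t0 + pd.to_timedelta(rng.uniform(0, 20 * 86400, n), unit="s")
    df = pd.DataFrame({
        "tag_id": rng.integers(1, n_tags + 1, n).astype(str),
        "receiver_id": rng.choice(recs, n),
        "timestamp": ts,
    })
    return df.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
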