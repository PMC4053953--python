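import numpy as np
import pandas as pd
import pytest

from wescnv.emrc import EMRCProfile


@pytest.fixture
def three_target_bed(tmp_path):
    """Three disjoint targets on two chromosomes, sizes 90/140/45 bp."""
    path = tmp_path / "targets.bed"
    path.write_text(
        "chr1\t100\t190\tt1\n"
        "chr1\t500\t640\tt2\n"
        "chr2\t20\t65\tt3\n"
    )
    return path


@pytest.fixture
def annotated_targets():
    """A small annotated target table with varied covariates."""
    rng = np.random.default_rng(11)
    n = 60
    starts = np.arange(n) * 2000 + 100
    sizes = rng.integers(60, 400, n)
    df = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + sizes,
        "id": [f"t{i}" for i in range(n)],
        "gc_percent": rng.integers(25, 75, n),
        "mappability": np.round(rng.uniform(0.3, 1.0, n), 3),
    })
    df["size_bp"] = df["end"] - df["start"]
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df


def make_profile(targets, emrc_values, sample_id="s"):
    emrc_values = np.asarray(emrc_values, dtype=float)
    sizes = (targets["end"] - targets["start"]).to_numpy()
    rc = np.rint(emrc_values * sizes).astype(int)
    return EMRCProfile(targets=targets, rc=rc, emrc=emrc_values, sample_id=sample_id)


@pytest.fixture
def flat_profile(annotated_targets):
    """Covariate-independent density: nothing for normalization to fix."""
    return make_profile(annotated_targets, np.full(len(annotated_targets), 2.0))
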