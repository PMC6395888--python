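import numpy as np
import pytest

import indelprof as ip
from indelprof import models


def make_site(
    protospacer="ACGTACGTACGTACGTACGT",
    pam="AGG",
    strand="+",
    upstream=None,
    downstream=None,
    site_id="s1",
):
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    upstream = upstream or "".join(rng.choice(bases, size=60))
    downstream = downstream or "".join(rng.choice(bases, size=60))
    return ip.TargetSite.from_guide_window(
        site_id=site_id, gene="G1", protospacer=protospacer, pam=pam,
        strand=strand, ref_name=f"amp_{site_id}",
        upstream_flank=upstream, downstream_flank=downstream,
    )


@pytest.fixture
def site():
    return make_site()


@pytest.fixture
def minus_site():
    return make_site(strand="-", site_id="s2")


@pytest.fixture(scope="session")
def clean_params():
    return ip.RepairTruthParams(substitution_error_rate=0.0, noise_indel_rate=0.0)


@pytest.fixture(scope="session")
def planted_cohort():
    """600 sites whose commonest-indel frequency is driven by the -4 base
    (four distinct levels), with a smaller -5 'C' bonus and Gaussian noise
    (SD 0.05) — the planted analogue of the precision-core hierarchy."""
    rng = np.random.default_rng(0)
    sites = ip.make_target_sites(600, seed=0)
    levels = {"T": 0.56, "A": 0.42, "C": 0.35, "G": 0.21}
    y = np.array(
        [
            float(
                np.clip(
                    levels[s.minus4_base]
                    + 0.04 * (s.protospacer[15] == "C")
                    + rng.normal(0, 0.05),
                    1e-3,
                    1.0,
                )
            )
            for s in sites
        ]
    )
    seqs = [models.site_to_sequence(s) for s in sites]
    X = models.one_hot_encode(seqs)
    idx = rng.permutation(len(y))
    n_train = int(round(0.8 * len(y)))
    return {
        "sites": sites, "seqs": seqs, "X": X, "y": y,
        "train": idx[:n_train], "test": idx[n_train:],
    }


@pytest.fixture(scope="session")
def planted_ann(planted_cohort):
    c = planted_cohort
    ann = models.PrecisionANN(random_state=1).fit(c["X"][c["train"]], c["y"][c["train"]])
    return ann
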