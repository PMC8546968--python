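import io as std_io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from mmvdbiome import CohortConfig, simulate_cohort
from mmvdbiome import diversity as dv
from mmvdbiome import dysbiosis as di_mod


@pytest.fixture(scope="session")
def default_cohort():
    """Full synthetic cohort under the default study conditions."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_analysis(default_cohort):
    """Rarefied counts, alpha diversity and DI for the default cohort."""
    c = default_cohort
    rarefied, dropped = dv.rarefy_table(c.otu_table, seed=7)
    alpha = dv.alpha_diversity(rarefied, c.tree)
    md = c.metadata.loc[alpha.index]
    labels = md["stage"].map({"A": "normal", "CD": "dysbiotic"}).dropna()
    ref = di_mod.fit_reference(c.qpcr.loc[labels.index], labels)
    di = di_mod.compute_di(c.qpcr, ref)
    return {"rarefied": rarefied, "dropped": dropped, "alpha": alpha,
            "metadata": md, "di": di, "reference": ref}


@pytest.fixture
def hand_tree():
    """((A:1,B:2):1,C:4); -- 3 tips, 4 edges, total length 8."""
    return TreeNode.read(std_io.StringIO("((A:1,B:2):1,C:4);"))


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced cohort for fast statistical checks."""
    return CohortConfig(
        group_sizes={"A": 8, "B1": 8, "B2": 8, "CD": 8},
        n_otus=40,
        depth_median=3000,
    )


def make_metadata(group_sizes, age_means, age_sd, rng):
    """Minimal metadata frame for bootstrap simulations."""
    rows = []
    for s, n in group_sizes.items():
        for i in range(n):
            rows.append({
                "sample_id": f"{s}{i+1:03d}", "stage": s,
                "age": max(rng.normal(age_means[s], age_sd), 1.0),
                "body_weight": max(rng.normal(9.0, 2.0), 2.0),
                "bcs": float(np.clip(rng.normal(5.4, 0.8), 1, 9)),
                "sex": "M" if rng.random() < 0.5 else "F",
            })
    return pd.DataFrame(rows).set_index("sample_id")
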