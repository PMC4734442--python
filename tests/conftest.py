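import numpy as np
import pandas as pd
import pytest

from bimaxgsea import ExpressionStudy


def make_meta(study_id, conditions, n_rep=2, control="CTRL", control_group="cg1"):
    """Sample metadata for one study: one control plus treated conditions."""
    rows = []
    for cond in [control] + list(conditions):
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{study_id}_{cond}_r{r}",
                    "study_id": study_id,
                    "condition_id": cond,
                    "is_control": cond == control,
                    "control_group": control_group,
                    "replicate_id": f"r{r}",
                    "dose": 0.0,
                }
            )
    return pd.DataFrame(rows)


def make_study(study_id, gene_fc, conditions, n_rep=2, noise_sd=0.0, seed=0):
    """Study whose preprocessed fold changes equal ``gene_fc`` (genes x conditions)."""
    rng = np.random.default_rng(seed)
    meta = make_meta(study_id, conditions, n_rep=n_rep)
    genes = list(gene_fc.index)
    probes = [f"p_{g}" for g in genes]
    cols = {}
    for _, row in meta.iterrows():
        base = np.zeros(len(genes))
        if not row["is_control"]:
            base = gene_fc[row["condition_id"]].to_numpy(dtype=float)
        cols[row["sample_id"]] = base + rng.normal(0, noise_sd, len(genes))
    values = pd.DataFrame(cols, index=probes)
    annotation = pd.DataFrame({"probe_id": probes, "gene_symbol": genes})
    return ExpressionStudy(
        study_id=study_id, values=values, meta=meta, annotation=annotation
    )


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
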