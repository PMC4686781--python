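import numpy as np
import pandas as pd
import pytest

import reprogkit as rk


@pytest.fixture
def tiny_matrix() -> rk.CountMatrix:
    return rk.CountMatrix(
        pd.DataFrame({"s1": [1, 3], "s2": [2, 4]}, index=pd.Index(["g1", "g2"], name="gene_id"))
    )


@pytest.fixture
def study_sheet() -> rk.SampleSheet:
    """The 15-sample layout: one fibroblast, two ES and two iPS lines,
    three replicates each."""
    rows = []
    for line, cls in (("EF", "fibroblast"), ("ES1", "es"), ("ES2", "es"),
                      ("iPS1", "ips"), ("iPS2", "ips")):
        for rep in (1, 2, 3):
            rows.append((f"{line}_r{rep}", line, cls, rep))
    return rk.SampleSheet(pd.DataFrame(rows, columns=["sample_id", "line_id", "cell_class", "replicate"]))


@pytest.fixture(scope="session")
def default_experiment():
    """One strong-signal synthetic experiment, shared across the session."""
    cfg = rk.default_config()
    counts, sheet, truth = rk.generate_experiment(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture(scope="session")
def default_run(default_experiment):
    """Full pipeline (de, classify, explore) on the default experiment."""
    cfg, counts, sheet, truth = default_experiment
    de_stage = rk.run_de(counts, sheet)
    cls_stage = rk.run_classify(de_stage, sheet)
    ex_stage = rk.run_explore(counts, sheet, de_stage.size_factors)
    return {
        "cfg": cfg,
        "counts": counts,
        "sheet": sheet,
        "truth": truth,
        "de": de_stage,
        "classify": cls_stage,
        "explore": ex_stage,
    }


def recovery_rate(truth, labels: pd.DataFrame, line: str) -> float:
    """Fraction of planted signature genes whose pipeline category matches
    the planted category for one iPS line (genes the pipeline missed from
    the signature set count as errors)."""
    planted = truth.table.loc[truth.table["is_signature"], f"category_{line}"]
    assigned = labels[labels["ips_line"] == line].set_index("gene_id")["category"]
    return float((assigned.reindex(planted.index) == planted).mean())


def simulate_two_groups(rng, n_genes, mean_a, mean_b, dispersion, reps=3, libs=None):
    """NB counts for a 2-line (fibroblast + es) mini-experiment."""
    rows, cols = [], {}
    for line, cls, mu in (("A", "fibroblast", mean_a), ("B", "es", mean_b)):
        for rep in range(1, reps + 1):
            s = 1.0 if libs is None else rng.uniform(*libs)
            mean = np.broadcast_to(np.asarray(mu, dtype=float) * s, (n_genes,))
            if dispersion == 0:
                k = rng.poisson(mean)
            else:
                size = 1.0 / dispersion
                k = rng.negative_binomial(size, size / (size + mean))
            cols[f"{line}_r{rep}"] = k
            rows.append((f"{line}_r{rep}", line, cls, rep))
    matrix = rk.CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]))
    sheet = rk.SampleSheet(pd.DataFrame(rows, columns=["sample_id", "line_id", "cell_class", "replicate"]))
    return matrix, sheet
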