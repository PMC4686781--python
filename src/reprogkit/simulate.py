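"""Synthetic RNA-seq experiment generator with planted ground truth.

Emulates the study design downstream stages expect: one embryonic-
fibroblast (EF) line, two embryonic-stem (ES) lines and two iPS lines,
each sequenced in three independent replicates (15 samples).  Counts are
negative-binomially distributed around per-(gene, line) means scaled by
per-sample library-size factors, matching the variance model the DE
engine fits (Var = mu + alpha * mu**2).

A configurable fraction of genes form an EF-vs-ES signature with a fixed
|log2 fold change|; each signature gene is planted, per iPS line, in one
of the four reprogramming categories:

* ``correct``          — iPS mean equals the ES mean,
* ``not_reprogrammed`` — iPS mean equals the EF mean (somatic memory),
* ``intermediate``     — iPS mean at the geometric midpoint of EF and ES,
* ``novel``            — iPS mean a fixed factor outside the EF-ES interval
  (by default overshooting past the ES level: excess activation or
  repression during the switch).

Reprogramming fates are largely locus-intrinsic (somatic-memory genes
recur across independently derived iPS lines), so by default a planted
category is shared by all iPS lines with probability
``category_concordance`` and drawn line-specifically otherwise.

The planted truth table is the oracle for recovery testing: a pipeline
run on generated data can be scored gene-by-gene against what was planted.
One seed drives everything through named child streams, so outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .classify import Category
from .io import CountMatrix, SampleSheet

EF_LINE = "EF"
ES_LINES = ("ES1", "ES2")
IPS_LINES = ("iPS1", "iPS2")

_CATEGORIES = (
    Category.CORRECT.value,
    Category.INTERMEDIATE.value,
    Category.NOT_REPROGRAMMED.value,
    Category.NOVEL.value,
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the strong-signal configuration.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the log-normal
    distribution of baseline expression (natural-log scale; the default
    centers the median at 200 counts).  ``signature_log2fc`` is the
    planted |log2 fold change| between EF and ES for signature genes.
    ``es_line_effect`` multiplies the second ES line's means so the two
    ES references can be made non-identical; the default 1.0 makes them
    near-replicates, as in a well-matched pair of ES lines.

    ``category_concordance`` is the probability that a signature gene's
    reprogramming fate is gene-intrinsic (the same category planted in
    every iPS line); ``novel_direction`` is ``"overshoot"`` (novel genes
    continue past the ES level by ``novel_factor``) or ``"random"``
    (either side of the EF-ES interval).
    """

    n_genes: int = 6000
    n_signature: int = 1500
    category_proportions: tuple[float, float, float, float] = (0.80, 0.07, 0.07, 0.06)
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    signature_log2fc: float = 4.0
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (0.7, 1.4)
    replicates: int = 3
    es_line_effect: float = 1.0
    novel_factor: float = 4.0
    novel_direction: str = "overshoot"
    category_concordance: float = 0.8
    n_ips_lines: int = 2
    seed: int = 7

    def validate(self) -> None:
        if self.n_genes < 1 or not (0 <= self.n_signature <= self.n_genes):
            raise ValueError("need 0 <= n_signature <= n_genes, n_genes >= 1")
        props = np.asarray(self.category_proportions, dtype=float)
        if len(props) != 4 or (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise ValueError("category proportions must be 4 non-negatives summing to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (variance estimation needs replication)")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be positive with lo <= hi")
        if self.es_line_effect <= 0 or self.novel_factor <= 1:
            raise ValueError("es_line_effect must be > 0 and novel_factor > 1")
        if self.novel_direction not in ("overshoot", "random"):
            raise ValueError("novel_direction must be 'overshoot' or 'random'")
        if not (0.0 <= self.category_concordance <= 1.0):
            raise ValueError("category_concordance must lie in [0, 1]")
        if self.n_ips_lines < 1:
            raise ValueError("need at least one iPS line")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")


def default_config(seed: int = 7) -> SimConfig:
    """The documented strong-signal configuration used by recovery tests."""
    cfg = SimConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene state: signature flag, group means, per-iPS-line
    category.  ``table`` is indexed by gene id with columns
    ``is_signature``, ``mu_ef``, ``mu_es1``, ``mu_es2`` and, per iPS line
    L, ``category_L`` (empty for background genes) and ``mu_L``."""

    table: pd.DataFrame
    ips_lines: tuple[str, ...]

    def planted_categories(self, line: str) -> pd.Series:
        sig = self.table[self.table["is_signature"]]
        return sig[f"category_{line}"]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Draw NB counts with the mean/dispersion parameterization
    Var = mean + alpha * mean**2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_experiment(cfg: SimConfig) -> tuple[CountMatrix, SampleSheet, SyntheticTruth]:
    """Generate (counts, sample sheet, planted truth) for one experiment.

    Deterministic given ``cfg.seed``: all randomness flows from named
    child streams of a single seed sequence.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    means_rng, cat_rng, lib_rng, count_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i:06d}" for i in range(1, n + 1)], name="gene_id")
    baseline = means_rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    is_sig = np.zeros(n, dtype=bool)
    sig_idx = means_rng.choice(n, size=cfg.n_signature, replace=False)
    is_sig[sig_idx] = True
    direction = means_rng.choice([-1.0, 1.0], size=n)  # sign of the EF -> ES change

    mu_ef = baseline.copy()
    mu_es1 = np.where(is_sig, baseline * 2.0 ** (direction * cfg.signature_log2fc), baseline)
    mu_es2 = np.where(is_sig, mu_es1 * cfg.es_line_effect, baseline)
    mu_es_gm = np.sqrt(mu_es1 * mu_es2)

    ips_lines = IPS_LINES[: cfg.n_ips_lines] if cfg.n_ips_lines <= len(IPS_LINES) else tuple(
        f"iPS{i + 1}" for i in range(cfg.n_ips_lines)
    )
    lo_ref = np.minimum(mu_ef, mu_es_gm)
    hi_ref = np.maximum(mu_ef, mu_es_gm)

    truth = pd.DataFrame(
        {"is_signature": is_sig, "mu_ef": mu_ef, "mu_es1": mu_es1, "mu_es2": mu_es2},
        index=gene_ids,
    )
    line_means: dict[str, np.ndarray] = {EF_LINE: mu_ef, ES_LINES[0]: mu_es1, ES_LINES[1]: mu_es2}
    intrinsic = cat_rng.random(n) < cfg.category_concordance
    intrinsic_cat = cat_rng.choice(len(_CATEGORIES), size=n, p=list(cfg.category_proportions))
    intrinsic_up = cat_rng.random(n) < 0.5
    for line in ips_lines:
        line_cat = cat_rng.choice(len(_CATEGORIES), size=n, p=list(cfg.category_proportions))
        line_up = cat_rng.random(n) < 0.5
        cats = np.where(intrinsic, intrinsic_cat, line_cat)
        novel_up = np.where(intrinsic, intrinsic_up, line_up)
        mu_ips = baseline.copy()
        planted = np.full(n, "", dtype=object)
        for k, cat in enumerate(_CATEGORIES):
            sel = is_sig & (cats == k)
            planted[sel] = cat
            if cat == Category.CORRECT.value:
                mu_ips[sel] = mu_es_gm[sel]
            elif cat == Category.NOT_REPROGRAMMED.value:
                mu_ips[sel] = mu_ef[sel]
            elif cat == Category.INTERMEDIATE.value:
                mu_ips[sel] = np.sqrt(mu_ef[sel] * mu_es_gm[sel])
            elif cfg.novel_direction == "overshoot":
                # continue past the ES level in the direction of the EF -> ES change
                mu_ips[sel] = mu_es_gm[sel] * cfg.novel_factor ** direction[sel]
            else:  # random side of the EF-ES interval
                up = sel & novel_up
                down = sel & ~novel_up
                mu_ips[up] = hi_ref[up] * cfg.novel_factor
                mu_ips[down] = lo_ref[down] / cfg.novel_factor
        truth[f"category_{line}"] = planted
        truth[f"mu_{line}"] = mu_ips
        line_means[line] = mu_ips

    lines = [EF_LINE, *ES_LINES, *ips_lines]
    sheet_rows = []
    columns = {}
    lo, hi = cfg.libsize_range
    for line in lines:
        cls = "fibroblast" if line == EF_LINE else ("es" if line in ES_LINES else "ips")
        for rep in range(1, cfg.replicates + 1):
            sample = f"{line}_r{rep}"
            s_j = lib_rng.uniform(lo, hi)
            sheet_rows.append((sample, line, cls, rep))
            columns[sample] = _nb_sample(count_rng, s_j * line_means[line], cfg.dispersion)

    counts = CountMatrix(pd.DataFrame(columns, index=gene_ids))
    sheet = SampleSheet(pd.DataFrame(sheet_rows, columns=["sample_id", "line_id", "cell_class", "replicate"]))
    return counts, sheet, SyntheticTruth(table=truth, ips_lines=tuple(ips_lines))


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")


def config_as_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["category_proportions"] = list(d["category_proportions"])
    d["libsize_range"] = list(d["libsize_range"])
    return d
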