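"""Stage orchestration: contrast enumeration and the de -> classify ->
explore chain, shared by the command-line interface and by tests.

The contrast set is derived mechanically from the sample sheet: the
fibroblast line against each ES line, and each iPS line against the
fibroblast line and both ES lines.  The classifier's rules are written
against exactly two ES references; sheets with more ES lines must name
the two to use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import classify as cls
from . import de, explore
from .io import CountMatrix, InputValidationError, SampleSheet, check_samples_match

logger = logging.getLogger(__name__)


def contrast_label(line_b: str, line_a: str) -> str:
    return f"{line_b}_vs_{line_a}"


def enumerate_contrasts(sheet: SampleSheet, es_pool: tuple[str, str] | None = None
                        ) -> list[de.ContrastSpec]:
    """EF vs each ES, then each iPS vs EF / ES1 / ES2.

    In every contrast the reference (group a) is the line named second in
    the label, so fold changes read "b relative to a".
    """
    ef = sheet.fibroblast_line
    es = sheet.es_lines
    if es_pool is not None:
        missing = [e for e in es_pool if e not in es]
        if missing:
            raise InputValidationError(f"es_pool lines not in sheet: {missing}")
        es = list(es_pool)
    if len(es) != 2:
        raise InputValidationError(
            f"classification needs exactly 2 ES reference lines, found {len(es)}: {es}"
            " (use es_pool to pick two)"
        )
    contrasts = []
    for e in es:
        contrasts.append(de.ContrastSpec(
            tuple(sheet.samples_of_line(ef)), tuple(sheet.samples_of_line(e)),
            contrast_label(e, ef)))
    for ips in sheet.ips_lines:
        for ref in (ef, *es):
            contrasts.append(de.ContrastSpec(
                tuple(sheet.samples_of_line(ref)), tuple(sheet.samples_of_line(ips)),
                contrast_label(ips, ref)))
    return contrasts


@dataclass(frozen=True)
class DEStage:
    size_factors: pd.Series
    dispersions: pd.Series
    results: dict[str, de.DEResult]  # keyed by contrast label
    es_lines: tuple[str, str]


def run_de(matrix: CountMatrix, sheet: SampleSheet,
           es_pool: tuple[str, str] | None = None) -> DEStage:
    """Size factors, dispersions and all standard contrasts."""
    check_samples_match(matrix, sheet)
    contrasts = enumerate_contrasts(sheet, es_pool)
    s = de.estimate_size_factors(matrix)
    d = de.estimate_dispersions(matrix, s, sheet)
    results = {c.label: de.nb_wald_test(matrix, s, d, c) for c in contrasts}
    es = sheet.es_lines if es_pool is None else list(es_pool)
    return DEStage(size_factors=s, dispersions=d, results=results,
                   es_lines=(es[0], es[1]))


@dataclass(frozen=True)
class ClassifyStage:
    signature: cls.SignatureGeneSet
    labels: pd.DataFrame
    per_line_counts: pd.DataFrame
    shared: dict[str, int] | None
    report: cls.ClassificationReport


def run_classify(stage: DEStage, sheet: SampleSheet,
                 alpha_sig: float = cls.DEFAULT_ALPHA_SIG,
                 decimals: int = 2) -> ClassifyStage:
    """Signature selection, per-iPS-line classification and the report."""
    ef = sheet.fibroblast_line
    es1, es2 = stage.es_lines
    de_es1 = stage.results[contrast_label(es1, ef)]
    de_es2 = stage.results[contrast_label(es2, ef)]
    signature = cls.select_signature_genes(de_es1, de_es2, alpha_sig)
    logger.info("signature: %d genes significant vs either ES line", len(signature))

    ips_tests = {}
    for ips in sheet.ips_lines:
        t_ef = stage.results[contrast_label(ips, ef)].table
        t_es1 = stage.results[contrast_label(ips, es1)].table
        t_es2 = stage.results[contrast_label(ips, es2)].table
        ips_tests[ips] = pd.DataFrame({
            "q_vs_ef": t_ef["qvalue"],
            "q_vs_es1": t_es1["qvalue"],
            "q_vs_es2": t_es2["qvalue"],
            "mu_ips": t_ef["base_mean_b"],
        })
    labels = cls.classify_all(signature, ips_tests, alpha_sig)
    counts = cls.category_counts(labels)
    shared = cls.shared_categories(labels) if len(sheet.ips_lines) >= 2 else None
    report = cls.build_report(counts, shared, total=len(signature), decimals=decimals)
    return ClassifyStage(signature=signature, labels=labels,
                         per_line_counts=counts, shared=shared, report=report)


@dataclass(frozen=True)
class ExploreStage:
    transformed: pd.DataFrame
    top_genes: list[str]
    dendrogram: explore.Dendrogram
    pca: explore.PCAResult


def run_explore(matrix: CountMatrix, sheet: SampleSheet,
                size_factors: pd.Series | None = None,
                top_k: int = 100, n_components: int = 2) -> ExploreStage:
    """Top-variance gene selection, clustering and PCA of samples."""
    check_samples_match(matrix, sheet)
    if size_factors is None:
        size_factors = de.estimate_size_factors(matrix)
    t = explore.transform_counts(matrix, size_factors)
    top = explore.top_variance_genes(t, top_k)
    sub = t.loc[top]
    dend = explore.cluster_samples(sub)
    pca = explore.pca_samples(sub, n_components=n_components)
    return ExploreStage(transformed=t, top_genes=top, dendrogram=dend, pca=pca)
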