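"""Cohort stratification and signature-enrichment testing.

Samples are stratified by gene mutation status (mutant iff they carry at least
one frameshift deletion, frameshift insertion or nonsense variant in the gene)
and by expression tertile (top third High, bottom third Low, middle Excluded).
Signature exposures are then compared between the WT/High stratum and each of
the other strata with a two-sided rank test, Bonferroni-adjusted over the
signature set.

The default rank test is the two-sample Mann-Whitney rank-sum: the strata are
independent groups of unequal size, for which a signed-rank test is undefined.
A paired signed-rank mode is available for genuinely paired designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SOMATIC_CONSEQUENCES = frozenset(
    {"frameshift_deletion", "frameshift_insertion", "nonsense"}
)

STRATA = ("WT/High", "WT/Low", "MT/High", "MT/Low")
CONTRASTS = (("WT/High", "WT/Low"), ("WT/High", "MT/High"), ("WT/High", "MT/Low"))


@dataclass
class SampleProfile:
    sample_id: str
    exposures: dict[str, float] = field(default_factory=dict)
    gene_status: dict[str, str] = field(default_factory=dict)  # gene -> "mutant"|"wildtype"
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sig, v in self.exposures.items():
            if v < 0:
                raise ValueError(f"negative exposure for {sig} in {self.sample_id}")


@dataclass(frozen=True)
class StratumLabel:
    gene: str
    status: str  # "WT" | "MT"
    expression_class: str  # "High" | "Low" | "Excluded"

    @property
    def key(self) -> str:
        return f"{self.status}/{self.expression_class}"


@dataclass
class AssociationResult:
    signature: str
    contrast: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    group_medians: tuple[float, float]
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("adjusted p must not be below raw p")


def call_gene_status(variants: Iterable) -> str:
    """Mutant iff any variant is of one of the three somatic classes.

    ``variants`` may be VariantRecord-like objects (with ``.consequence``) or
    bare consequence strings.  No variants at all -> wildtype.
    """
    for v in variants:
        consequence = v if isinstance(v, str) else getattr(v, "consequence", "other")
        if consequence in SOMATIC_CONSEQUENCES:
            return "mutant"
    return "wildtype"


def stratify_expression(
    values: Mapping[str, float], mode: str = "tertile"
) -> dict[str, str]:
    """Assign High/Low/Excluded per sample from expression levels.

    Tertile mode (default): bottom third (<= empirical 1/3 quantile, linear
    interpolation) -> Low, top third (>= 2/3 quantile) -> High, middle ->
    Excluded.  Binary mode splits at the 33rd percentile with nothing excluded.
    All-identical values degenerate to all Excluded.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 samples to stratify")
    samples = list(values)
    arr = np.asarray([float(values[s]) for s in samples])
    if np.all(arr == arr[0]):
        logger.warning("constant expression values: all samples Excluded")
        return {s: "Excluded" for s in samples}
    if mode == "tertile":
        lo, hi = np.quantile(arr, [1.0 / 3.0, 2.0 / 3.0])
        out = {}
        for s, v in zip(samples, arr):
            if v <= lo:
                out[s] = "Low"
            elif v >= hi:
                out[s] = "High"
            else:
                out[s] = "Excluded"
        return out
    if mode == "binary":
        cut = np.quantile(arr, 0.33)
        return {s: ("Low" if v <= cut else "High") for s, v in zip(samples, arr)}
    raise ValueError(f"unknown stratification mode: {mode!r}")


def assign_strata(
    profiles: Sequence[SampleProfile], gene: str, mode: str = "tertile"
) -> dict[str, StratumLabel]:
    """One StratumLabel per sample for ``gene`` (status x expression class)."""
    expr = {}
    for p in profiles:
        if gene in p.expression:
            expr[p.sample_id] = p.expression[gene]
        else:
            logger.warning("sample %s has no expression for %s", p.sample_id, gene)
    classes = stratify_expression(expr, mode=mode) if expr else {}
    labels = {}
    for p in profiles:
        status_raw = p.gene_status.get(gene)
        if status_raw is None:
            logger.info("sample %s has no %s status; treating as wildtype", p.sample_id, gene)
            status_raw = "wildtype"
        status = "MT" if status_raw == "mutant" else "WT"
        labels[p.sample_id] = StratumLabel(
            gene=gene,
            status=status,
            expression_class=classes.get(p.sample_id, "Excluded"),
        )
    return labels


def test_signature_association(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided rank test between two exposure groups -> (statistic, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


test_signature_association.__test__ = False  # not a pytest case


def adjust_bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """p_adj = min(1, p * m); m defaults to len(p_values) and must cover it."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return [min(1.0, v * m) for v in p]


def correlate_exposures(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p for paired exposure vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an exposure vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class EnrichmentReport:
    gene: str
    proportions: pd.DataFrame  # strata x signatures, mean exposure proportion
    associations: list[AssociationResult]
    flagged: list[str]
    stratum_sizes: dict[str, int]
    skipped_contrasts: list[tuple[str, str]]

    def associations_frame(self) -> pd.DataFrame:
        rows = [
            {
                "signature": r.signature,
                "contrast": f"{r.contrast[0]} vs {r.contrast[1]}",
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "median_a": r.group_medians[0],
                "median_b": r.group_medians[1],
                "n_a": r.n_per_group[0],
                "n_b": r.n_per_group[1],
            }
            for r in self.associations
        ]
        return pd.DataFrame(rows)


def enrichment_report(
    profiles: Sequence[SampleProfile],
    gene: str,
    signatures: Sequence[str],
    m: int | None = None,
    alpha: float = 0.05,
    mode: str = "tertile",
    normalize: bool = True,
) -> EnrichmentReport:
    """Per-stratum exposure proportions plus rank-test enrichment calls.

    For each signature the WT/High stratum is contrasted against WT/Low,
    MT/High and MT/Low; p-values are Bonferroni-adjusted with m defaulting to
    the number of signatures tested.  A signature is flagged when every
    contrast is significant at ``alpha`` post-adjustment and its WT/High median
    exceeds the other stratum's median (enrichment, not depletion).
    """
    signatures = list(signatures)
    for p in profiles:
        missing = [s for s in signatures if s not in p.exposures]
        if missing:
            raise KeyError(f"sample {p.sample_id} lacks exposures: {missing[:3]}")
    labels = assign_strata(profiles, gene, mode=mode)

    mat = pd.DataFrame(
        {s: [p.exposures[s] for p in profiles] for s in signatures},
        index=[p.sample_id for p in profiles],
        dtype=float,
    )
    if normalize:
        totals = mat.sum(axis=1)
        nz = totals > 0
        mat.loc[nz] = mat.loc[nz].div(totals[nz], axis=0)

    members = {k: [] for k in STRATA}
    for p in profiles:
        key = labels[p.sample_id].key
        if key in members:
            members[key].append(p.sample_id)
    stratum_sizes = {k: len(v) for k, v in members.items()}

    proportions = pd.DataFrame(
        {
            k: (mat.loc[v].mean(axis=0) if v else pd.Series(np.nan, index=signatures))
            for k, v in members.items()
        }
    ).T
    proportions.index.name = "stratum"

    if m is None:
        m = len(signatures)
    associations: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []
    raw: list[tuple[str, tuple[str, str], float, float, tuple, tuple]] = []
    for sig in signatures:
        for ka, kb in CONTRASTS:
            va = mat.loc[members[ka], sig].to_numpy() if members[ka] else np.array([])
            vb = mat.loc[members[kb], sig].to_numpy() if members[kb] else np.array([])
            if va.size == 0 or vb.size == 0:
                if (ka, kb) not in skipped:
                    logger.warning("empty stratum, skipping contrast %s vs %s", ka, kb)
                    skipped.append((ka, kb))
                continue
            stat, p_raw = test_signature_association(va, vb)
            raw.append(
                (
                    sig,
                    (ka, kb),
                    stat,
                    p_raw,
                    (float(np.median(va)), float(np.median(vb))),
                    (int(va.size), int(vb.size)),
                )
            )
    # Bonferroni m covers the signature family (the paper's 82); each signature
    # contributes up to three contrasts which are required jointly, so the
    # family multiplier is the signature count, not the contrast count.
    adjusted = [min(1.0, r[3] * m) for r in raw]
    for (sig, contrast, stat, p_raw, medians, ns), p_adj in zip(raw, adjusted):
        associations.append(
            AssociationResult(
                signature=sig,
                contrast=contrast,
                statistic=stat,
                p_raw=p_raw,
                p_adjusted=p_adj,
                group_medians=medians,
                n_per_group=ns,
            )
        )

    tested_contrasts = [c for c in CONTRASTS if c not in skipped]
    flagged = []
    if tested_contrasts:
        for sig in signatures:
            sig_res = [r for r in associations if r.signature == sig]
            if len(sig_res) == len(tested_contrasts) and all(
                r.p_adjusted < alpha and r.group_medians[0] > r.group_medians[1]
                for r in sig_res
            ):
                flagged.append(sig)
    return EnrichmentReport(
        gene=gene,
        proportions=proportions,
        associations=associations,
        flagged=flagged,
        stratum_sizes=stratum_sizes,
        skipped_contrasts=skipped,
    )
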