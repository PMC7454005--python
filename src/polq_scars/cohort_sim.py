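"""Synthetic cohorts with known enrichment truth.

Exposure vectors are drawn as Dirichlet proportions (one concentration per
signature) scaled by a log-normal per-sample mutation burden.  Enrichment is
planted multiplicatively on the Dirichlet concentration of chosen signatures,
restricted to one stratum of the target gene (e.g. "WT/High"), so recovery by
the rank tests in :mod:`polq_scars.cohort` can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import STRATA, SampleProfile, assign_strata, enrichment_report

DEFAULT_SIGNATURES = tuple(
    [f"SBS{i}" for i in range(1, 66)] + [f"ID{i}" for i in range(1, 18)]
)


@dataclass
class CohortSimSpec:
    n_samples: int = 400
    signatures: tuple[str, ...] = DEFAULT_SIGNATURES
    baseline_concentration: float | Mapping[str, float] = 2.0
    # signature -> (stratum key, fold change on its concentration)
    enriched: dict[str, tuple[str, float]] = field(default_factory=dict)
    gene: str = "POLQ"
    gene_prevalence: dict[str, float] = field(default_factory=lambda: {"POLQ": 0.5})
    expression_sigma: float = 1.0
    burden_mu: float = np.log(5000.0)
    burden_sigma: float = 0.5
    tertile_mode: str = "tertile"

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        for sig, (stratum, fold) in self.enriched.items():
            if sig not in self.signatures:
                raise ValueError(f"enriched signature {sig!r} not in signature set")
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            if fold <= 0:
                raise ValueError("fold changes must be > 0")
        for gene, prev in self.gene_prevalence.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence for {gene} must be in [0, 1]")
        if self.gene not in self.gene_prevalence:
            raise ValueError("target gene needs a prevalence entry")

    def concentrations(self) -> np.ndarray:
        if isinstance(self.baseline_concentration, Mapping):
            return np.array(
                [float(self.baseline_concentration[s]) for s in self.signatures]
            )
        return np.full(len(self.signatures), float(self.baseline_concentration))


@dataclass
class CohortTruth:
    strata: dict[str, str]  # sample_id -> stratum key for the target gene
    enriched: dict[str, tuple[str, float]]


def simulate_cohort(
    spec: CohortSimSpec, seed: int
) -> tuple[list[SampleProfile], CohortTruth]:
    """Draw a cohort; reproducible under ``seed``.

    Gene statuses and expression are drawn first, strata are derived with the
    same tertile rule the analysis uses, and only then are exposures drawn with
    the planted concentration shifts applied to the target stratum.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    genes = sorted(spec.gene_prevalence)

    status = {
        g: np.where(rng.random(n) < spec.gene_prevalence[g], "mutant", "wildtype")
        for g in genes
    }
    expression = {g: rng.lognormal(0.0, spec.expression_sigma, size=n) for g in genes}

    profiles = [
        SampleProfile(
            sample_id=sid,
            exposures={},
            gene_status={g: str(status[g][i]) for g in genes},
            expression={g: float(expression[g][i]) for g in genes},
        )
        for i, sid in enumerate(sample_ids)
    ]
    labels = assign_strata(profiles, spec.gene, mode=spec.tertile_mode)
    strata = {sid: labels[sid].key for sid in sample_ids}

    base = spec.concentrations()
    sig_index = {s: i for i, s in enumerate(spec.signatures)}
    burdens = rng.lognormal(spec.burden_mu, spec.burden_sigma, size=n)
    for i, p in enumerate(profiles):
        conc = base.copy()
        for sig, (stratum, fold) in spec.enriched.items():
            if strata[p.sample_id] == stratum:
                conc[sig_index[sig]] *= fold
        props = rng.dirichlet(conc)
        p.exposures = {
            s: float(props[j] * burdens[i]) for j, s in enumerate(spec.signatures)
        }
    return profiles, CohortTruth(strata=strata, enriched=dict(spec.enriched))


def profiles_to_tables(
    profiles: Sequence[SampleProfile],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(exposures, expression, status) tables in the TSV layouts the CLI reads."""
    idx = [p.sample_id for p in profiles]
    exposures = pd.DataFrame([p.exposures for p in profiles], index=idx)
    expression = pd.DataFrame([p.expression for p in profiles], index=idx)
    status = pd.DataFrame([p.gene_status for p in profiles], index=idx)
    for df in (exposures, expression, status):
        df.index.name = "sample_id"
    return exposures, expression, status


def recovery_suite(
    folds: Sequence[float],
    sizes: Sequence[int],
    replicates: int = 20,
    seed: int = 0,
    signature: str = "SBS3",
    stratum: str = "WT/High",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detection / false-flag rates over a (fold, n) grid.

    Each cell runs ``replicates`` independent simulate -> enrichment_report
    rounds.  detection = fraction of replicates flagging the planted signature
    (for fold 1 nothing is planted and detection is reported as NaN);
    false_flag = fraction flagging any non-planted signature.
    """
    if not list(folds) or not list(sizes):
        raise ValueError("grid must be non-empty")
    rows = []
    counter = 0
    for fold in folds:
        for n in sizes:
            detected = 0
            false_flagged = 0
            for _ in range(replicates):
                enriched = {} if fold == 1.0 else {signature: (stratum, float(fold))}
                spec = CohortSimSpec(n_samples=int(n), enriched=enriched)
                profiles, truth = simulate_cohort(spec, seed=seed + counter)
                counter += 1
                report = enrichment_report(
                    profiles, spec.gene, spec.signatures, alpha=alpha
                )
                if fold != 1.0 and signature in report.flagged:
                    detected += 1
                if set(report.flagged) - set(truth.enriched):
                    false_flagged += 1
            rows.append(
                {
                    "fold": float(fold),
                    "n": int(n),
                    "replicates": replicates,
                    "detection_rate": (np.nan if fold == 1.0 else detected / replicates),
                    "false_flag_rate": false_flagged / replicates,
                }
            )
    return pd.DataFrame(rows)
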