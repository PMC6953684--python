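"""Observed-vs-null inference: permutation p-values and effect sizes.

Each site's observed C-score is compared with its fixed-fixed null
ensemble. Both one-tailed p-values are reported simultaneously (the
"two-flow" reading: P(null >= observed) for segregation and
P(null <= observed) for aggregation), with ties counted in both tails and
the add-one correction p = (1 + k) / (n + 1), so p is never exactly zero.

Two effect sizes are carried side by side:

* NES = (observed - null mean) / null mean — the normalized effect size
  used for the stress-gradient regressions;
* SES = (observed - null mean) / null sd — the classical standardized
  effect size, reported for comparability with the wider null-model
  literature.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cscore import c_score
from .matrix import PresenceAbsenceMatrix
from .null_model import NullEnsemble, generate_null_ensemble, site_seed

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistributionSummary",
    "CoocResult",
    "RunConfig",
    "summarize_null",
    "tail_p_values",
    "effect_sizes",
    "analyze_site",
    "analyze_sites",
    "results_table",
    "write_results_tsv",
    "load_config",
]


@dataclass(frozen=True)
class NullDistributionSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        assert self.min <= self.mean + 1e-12 and self.mean <= self.max + 1e-12
        assert self.sd >= 0


@dataclass(frozen=True)
class CoocResult:
    """One site's co-occurrence test record (one row of the results table)."""

    site_id: str
    observed: float
    null_summary: NullDistributionSummary
    p_ge: float  # P(null >= observed): small => segregation
    p_le: float  # P(null <= observed): small => aggregation
    nes: float
    ses: float | None  # None when the null distribution has sd = 0
    degenerate: bool = False
    seed: int | None = None


@dataclass
class RunConfig:
    """Settings of a co-occurrence run (null-model knobs and master seed)."""

    n_null: int = 5_000
    burn_in: int = 30_000
    thin: int | None = None  # None => max(1000, 10*R*C) attempted swaps
    thin_unit: str = "attempts"
    seed: int = 0
    algorithm: str = "sequential_swap"
    alpha: float = 0.05


def summarize_null(e: NullEnsemble) -> NullDistributionSummary:
    """Sample mean, sd (n-1 denominator), min and max of the null statistic."""
    v = np.asarray(e.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty null ensemble")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return NullDistributionSummary(
        n=int(v.size), mean=float(v.mean()), sd=sd, min=float(v.min()), max=float(v.max())
    )


def tail_p_values(observed: float, e: NullEnsemble) -> tuple[float, float]:
    """Both one-tailed permutation p-values with add-one correction.

    p_ge = (1 + #{null >= observed}) / (n + 1) and symmetrically for p_le;
    ties count in both tails, so p_ge + p_le >= 1 always and the smallest
    attainable p is 1/(n+1) (0.0002 at n = 5000).
    """
    v = np.asarray(e.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty null ensemble")
    n = v.size
    p_ge = (1 + int((v >= observed).sum())) / (n + 1)
    p_le = (1 + int((v <= observed).sum())) / (n + 1)
    return p_ge, p_le


def effect_sizes(
    observed: float, s: NullDistributionSummary
) -> tuple[float, float | None]:
    """(NES, SES) = ((obs-mean)/mean, (obs-mean)/sd); SES is None when sd=0."""
    if s.mean == 0:
        raise ValueError("NES undefined: null mean is zero")
    nes = (observed - s.mean) / s.mean
    ses = (observed - s.mean) / s.sd if s.sd > 0 else None
    return nes, ses


def analyze_site(
    m: PresenceAbsenceMatrix,
    config: RunConfig | None = None,
    statistic=c_score,
) -> CoocResult:
    """Full observed-vs-null analysis of one site matrix.

    Composes the statistic, the fixed-fixed ensemble, the null summary,
    both tail p-values and both effect sizes. The per-site seed is derived
    from the master seed and the site label, so multi-site runs do not
    depend on analysis order. A rigid (degenerate) matrix yields p = 1,
    NES = SES = 0 and a flagged record rather than an error.
    """
    config = config or RunConfig()
    seed = site_seed(config.seed, m.site_id)
    observed = float(statistic(m.values))
    ensemble = generate_null_ensemble(
        m,
        statistic=statistic,
        n=config.n_null,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=seed,
        thin_unit=config.thin_unit,
    )
    summary = summarize_null(ensemble)
    if ensemble.degenerate:
        warnings.warn(f"site {m.site_id!r}: degenerate ensemble, reporting p=1, NES=0")
        return CoocResult(m.site_id, observed, summary, 1.0, 1.0, 0.0, 0.0, True, seed)
    p_ge, p_le = tail_p_values(observed, ensemble)
    nes, ses = effect_sizes(observed, summary)
    logger.info(
        "site %s: observed=%.4f null_mean=%.4f p_ge=%.4g p_le=%.4g (seed=%d)",
        m.site_id, observed, summary.mean, p_ge, p_le, seed,
    )
    return CoocResult(m.site_id, observed, summary, p_ge, p_le, nes, ses, False, seed)


def analyze_sites(
    matrices: Iterable[PresenceAbsenceMatrix], config: RunConfig | None = None
) -> list[CoocResult]:
    return [analyze_site(m, config) for m in matrices]


def results_table(results: Iterable[CoocResult]) -> pd.DataFrame:
    """Results as a table mirroring the per-site report layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "site": r.site_id,
                "null_min": r.null_summary.min,
                "null_max": r.null_summary.max,
                "observed": r.observed,
                "p_ge": r.p_ge,
                "p_le": r.p_le,
                "null_mean": r.null_summary.mean,
                "null_sd": r.null_summary.sd,
                "nes": r.nes,
                "ses": np.nan if r.ses is None else r.ses,
                "degenerate": r.degenerate,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(results: Iterable[CoocResult], path) -> None:
    results_table(results).to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def load_config(path) -> RunConfig:
    """Read a plain ``key = value`` config file into a :class:`RunConfig`."""
    cfg = RunConfig()
    casts = {
        "n_null": int, "burn_in": int, "thin": int, "seed": int,
        "alpha": float, "algorithm": str, "thin_unit": str,
    }
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in casts:
            raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
        setattr(cfg, key, casts[key](value))
    return cfg
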