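"""Phenotype tables, replicate aggregation, and herbicide reduction indices.

Phenotypes live in a long table with one row per
``(accession, environment, treatment, trait, replicate)`` observation.  The
treatment label ``"control"`` is reserved for untreated plots.  Each
``(environment, treatment, trait)`` combination is one analysis *context*:
an accession-aligned vector that feeds a single-context association scan.

The reduction index expresses the percentage loss of a trait under herbicide
relative to the same accession untreated::

    RI = 100 - 100 * treated / control

and may be negative when a treated plot outperforms its control.  Herbicide
damage scores (HDS, ordinal 1 = no damage to 5 = total mortality) are kept on
their 1-5 scale and analysed as quantitative values downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataFormatError

logger = logging.getLogger(__name__)

CONTROL_TREATMENT = "control"
PHENOTYPE_COLUMNS = [
    "accession_id", "environment", "treatment", "trait", "replicate", "value",
]

#: minimum non-missing phenotypes for a context to enter an association scan
MIN_CONTEXT_SAMPLES = 30

__all__ = [
    "CONTROL_TREATMENT",
    "MIN_CONTEXT_SAMPLES",
    "ContextVector",
    "validate_phenotypes",
    "read_phenotypes",
    "write_phenotypes",
    "aggregate_replicates",
    "reduction_index",
    "derive_ri_contexts",
]


@dataclass
class ContextVector:
    """Accession-aligned phenotype vector for one (env, treatment, trait)."""

    environment: str
    treatment: str
    trait: str
    values: pd.Series  # index: accession_id; NaN = unobserved

    @property
    def context_id(self) -> tuple[str, str, str]:
        return (self.environment, self.treatment, self.trait)

    @property
    def n_valid(self) -> int:
        return int(self.values.notna().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ContextVector({self.environment}/{self.treatment}/"
                f"{self.trait}, n_valid={self.n_valid}/{len(self.values)})")


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, key uniqueness, numeric values, and HDS range."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise DataFormatError(f"phenotype table lacks columns {missing}")
    table = table.copy()
    key = ["accession_id", "environment", "treatment", "trait", "replicate"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup, key].iloc[0].tolist()
        raise DataFormatError(f"duplicate phenotype record for {first}")
    try:
        table["value"] = pd.to_numeric(table["value"])
    except (ValueError, TypeError):
        bad = table[pd.to_numeric(table["value"], errors="coerce").isna()
                    & table["value"].notna()]
        ident = bad[key].iloc[0].tolist() if len(bad) else "?"
        raise DataFormatError(f"non-numeric phenotype value at record {ident}")
    hds = table["trait"].astype(str).str.upper().str.startswith("HDS")
    vals = table.loc[hds, "value"].dropna()
    if len(vals) and ((vals < 1) | (vals > 5)).any():
        raise DataFormatError("HDS values must lie on the ordinal 1-5 scale")
    return table


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def aggregate_replicates(
    table: pd.DataFrame,
    accession_ids: Iterable[str] | None = None,
) -> dict[tuple[str, str, str], ContextVector]:
    """Arithmetic mean over replicates per (accession, context).

    Stands in for a spatially adjusted BLUP stage: each accession's replicate
    observations within a context are averaged; accessions never observed in
    a context stay NaN but remain in the alignment.
    """
    table = validate_phenotypes(table)
    if accession_ids is None:
        accession_ids = sorted(table["accession_id"].astype(str).unique())
    accession_ids = [str(a) for a in accession_ids]
    means = (
        table.groupby(["environment", "treatment", "trait", "accession_id"])["value"]
        .mean()
    )
    contexts: dict[tuple[str, str, str], ContextVector] = {}
    for (env, trt, trait), grp in means.groupby(level=[0, 1, 2]):
        vec = grp.droplevel([0, 1, 2]).reindex(accession_ids)
        vec.index.name = "accession_id"
        contexts[(env, trt, trait)] = ContextVector(env, trt, trait, vec)
    return contexts


def reduction_index(treated_mean, control_mean):
    """Percent reduction ``100 - 100 * treated / control``.

    Accepts scalars or aligned arrays/Series.  A zero or missing control
    propagates NaN (logged) instead of raising; negative values mean the
    treated plot exceeded its control.
    """
    t = np.asarray(treated_mean, dtype=float)
    c = np.asarray(control_mean, dtype=float)
    invalid = np.isnan(c) | (c == 0.0)
    n_invalid = int(np.count_nonzero(invalid & ~np.isnan(t)))
    if n_invalid:
        logger.info("reduction_index: %d values dropped (control 0 or missing)",
                    n_invalid)
    with np.errstate(invalid="ignore", divide="ignore"):
        ri = np.where(invalid, np.nan, 100.0 - 100.0 * t / c)
    if np.isscalar(treated_mean) and np.isscalar(control_mean):
        return float(ri)
    if isinstance(treated_mean, pd.Series):
        return pd.Series(ri, index=treated_mean.index)
    return ri


def derive_ri_contexts(
    contexts: Mapping[tuple[str, str, str], ContextVector],
) -> dict[tuple[str, str, str], ContextVector]:
    """Per-accession reduction indices for every treated context with a control.

    For each (environment, treatment != control, trait) where the same
    environment has a ``control`` context for the trait, emits a new context
    with trait ``RI_<trait>`` holding per-accession reduction indices.
    Environments lacking a control are skipped with a warning; no accession
    is fabricated — the RI alignment is the treated context's alignment.
    """
    out: dict[tuple[str, str, str], ContextVector] = {}
    for (env, trt, trait), vec in contexts.items():
        if trt == CONTROL_TREATMENT or trait.startswith("RI_"):
            continue
        control = contexts.get((env, CONTROL_TREATMENT, trait))
        if control is None:
            logger.warning(
                "no control context for %s/%s in %s: RI skipped", trait, trt, env
            )
            continue
        ri = reduction_index(vec.values, control.values.reindex(vec.values.index))
        out[(env, trt, f"RI_{trait}")] = ContextVector(
            env, trt, f"RI_{trait}", ri
        )
    return out
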