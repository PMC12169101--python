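"""Schema, validation and site-averaging for paired abundance databases.

The input is a tidy long-format table: one row is the abundance of one taxon
at one site, annotated with the primary source (publication), the study
(location/year dataset within a source), the management system at the site
(or ``REFERENCE`` for undisturbed forest), taxonomic group, optional time
since harvest/establishment, continent and IUCN threat status.

The central preprocessing step is :func:`average_site_abundances`: per study
and per system, each taxon's abundance is averaged arithmetically across that
study's sites of that system, treating a taxon recorded at some sites but not
others as an observed zero at the sites where it is absent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .systems import (
    ANIMAL_GROUPS,
    REFERENCE,
    SYSTEMS,
    TAXON_GROUPS,
    THREAT_CATEGORIES,
    THREATENED,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "source_id",
    "study_id",
    "site_id",
    "system",
    "taxon_name",
    "taxon_group",
    "abundance",
)

OPTIONAL_COLUMNS = ("time_since_years", "continent", "threat_status")

KEY_COLUMNS = ("source_id", "study_id", "site_id", "system", "taxon_name_norm")


class SchemaError(ValueError):
    """A required column is missing or has the wrong structure."""


class ValidationError(ValueError):
    """Row-level contents violate an invariant; offending rows are listed."""


def normalize_taxon(name: str) -> str:
    """Normalize a taxon name for matching: trim, collapse whitespace, casefold.

    The original spelling is preserved elsewhere; this canonical form is used
    only for joins and duplicate detection.
    """
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


def is_genus_only(name: str) -> bool:
    """True when a normalized name lacks a second epithet (genus-level record)."""
    return len(normalize_taxon(name).split(" ")) < 2


def load_abundance_table(
    path: str | Path,
    *,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read and validate a delimited abundance table.

    Parameters
    ----------
    path:
        Delimited UTF-8 text file with a header row containing at least the
        required columns (source_id, study_id, site_id, system, taxon_name,
        taxon_group, abundance).
    delimiter:
        Field separator, comma by default.

    Returns
    -------
    DataFrame of validated records with an added ``taxon_name_norm`` column
    and, where absent, the optional columns filled with missing values.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If any row violates an invariant (negative abundance, unknown system
        or taxon group, duplicated key); the message lists offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"source_id": str, "study_id": str, "site_id": str})
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw abundance table and return the normalized copy.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("source_id", "study_id", "site_id"):
        df[col] = df[col].astype(str)

    problems: list[str] = []

    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    bad = df.index[abundance.isna() | (abundance < 0)]
    if len(bad):
        problems.append(
            "non-numeric or negative abundance at row(s): "
            + ", ".join(str(i + 1) for i in bad[:20])
        )
    df["abundance"] = abundance

    valid_systems = set(SYSTEMS) | {REFERENCE}
    bad = df.index[~df["system"].isin(valid_systems)]
    if len(bad):
        problems.append(
            "unknown system code at row(s): " + ", ".join(str(i + 1) for i in bad[:20])
        )

    bad = df.index[~df["taxon_group"].isin(TAXON_GROUPS)]
    if len(bad):
        problems.append(
            "unknown taxon_group at row(s): " + ", ".join(str(i + 1) for i in bad[:20])
        )

    df["taxon_name_norm"] = df["taxon_name"].map(normalize_taxon)

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        keys = (
            df.loc[dup, list(KEY_COLUMNS)]
            .drop_duplicates()
            .apply(lambda r: "/".join(map(str, r)), axis=1)
        )
        problems.append(
            "duplicated (source, study, site, system, taxon) key(s): "
            + "; ".join(keys.head(10))
        )

    ts = pd.to_numeric(df["time_since_years"], errors="coerce")
    bad = df.index[ts.notna() & (ts < 0)]
    if len(bad):
        problems.append(
            "negative time_since_years at row(s): "
            + ", ".join(str(i + 1) for i in bad[:20])
        )
    df["time_since_years"] = ts

    if "threat_status" in df.columns:
        status = df["threat_status"].where(df["threat_status"].notna(), np.nan)
        known = status.isna() | status.isin(THREAT_CATEGORIES)
        if not known.all():
            problems.append(
                "unknown threat_status at row(s): "
                + ", ".join(str(i + 1) for i in df.index[~known][:20])
            )

    if problems:
        raise ValidationError("; ".join(problems))
    return df


def write_abundance_table(df: pd.DataFrame, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a validated table back to delimited text (round-trip safe)."""
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in df.columns]
    df.to_csv(path, sep=delimiter, index=False, columns=cols)


@dataclass
class StudyCommunity:
    """Per-(study, system) community: mean abundance per taxon across sites.

    ``species_mean_abundance`` maps the normalized taxon name to the
    arithmetic mean abundance over the study's sites of this system, with
    taxa unrecorded at a site contributing zero for that site.
    """

    study_id: str
    source_id: str
    system: str
    species_mean_abundance: dict[str, float]
    n_sites: int
    taxon_group: str | None = None
    continent: str | None = None
    time_since_years: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def richness(self) -> int:
        return len(self.species_mean_abundance)

    @property
    def total_abundance(self) -> float:
        return float(sum(self.species_mean_abundance.values()))


def average_site_abundances(
    df: pd.DataFrame,
    *,
    exclusion_log: list[dict] | None = None,
) -> list[StudyCommunity]:
    """Collapse site-level records to per-(study, system) mean communities.

    A taxon observed at any site of a study x system is zero-filled at that
    group's other sites before averaging, so its mean is (sum of recorded
    abundances) / (number of sites sampled for that study x system).  Taxa
    whose mean is zero (possible only if every recorded value was zero) are
    dropped: a taxon never detected is absent, not present at density zero.

    Studies lacking a reference community are excluded with a logged warning
    (and a machine-readable entry appended to ``exclusion_log`` if given).
    """
    if "taxon_name_norm" not in df.columns:
        df = validate_records(df)

    communities: list[StudyCommunity] = []
    for (source_id, study_id), study_df in df.groupby(["source_id", "study_id"], sort=True):
        systems_here = set(study_df["system"])
        if REFERENCE not in systems_here:
            logger.warning("study %s/%s has no reference sites; excluded", source_id, study_id)
            if exclusion_log is not None:
                exclusion_log.append(
                    {"source_id": source_id, "study_id": study_id, "reason": "no_reference_sites"}
                )
            continue
        if systems_here == {REFERENCE}:
            logger.warning("study %s/%s has no managed sites; excluded", source_id, study_id)
            if exclusion_log is not None:
                exclusion_log.append(
                    {"source_id": source_id, "study_id": study_id, "reason": "no_managed_sites"}
                )
            continue
        for system, sys_df in study_df.groupby("system", sort=True):
            n_sites = sys_df["site_id"].nunique()
            # zero-fill: mean = sum over recorded sites / number of sites
            sums = sys_df.groupby("taxon_name_norm")["abundance"].sum()
            means = (sums / n_sites)[lambda s: s > 0]
            if means.empty:
                continue
            groups = sys_df["taxon_group"].unique()
            ts = sys_df["time_since_years"].dropna()
            cont = sys_df["continent"].dropna()
            communities.append(
                StudyCommunity(
                    study_id=str(study_id),
                    source_id=str(source_id),
                    system=str(system),
                    species_mean_abundance=means.to_dict(),
                    n_sites=int(n_sites),
                    taxon_group=groups[0] if len(groups) == 1 else None,
                    continent=cont.iloc[0] if len(cont) else None,
                    time_since_years=float(ts.iloc[0]) if len(ts) else None,
                )
            )
    return communities


def merge_threat_status(df: pd.DataFrame, redlist: pd.DataFrame) -> pd.DataFrame:
    """Fill ``threat_status`` by exact normalized binomial match.

    ``redlist`` needs columns ``binomial`` and ``category``.  Genus-only
    records never match; unmatched records keep a missing status.  The row
    count is unchanged.
    """
    if not {"binomial", "category"}.issubset(redlist.columns):
        raise SchemaError("red-list table requires columns: binomial, category")
    rl = redlist.copy()
    rl["binomial_norm"] = rl["binomial"].map(normalize_taxon)
    if rl["binomial_norm"].duplicated().any():
        dups = rl.loc[rl["binomial_norm"].duplicated(), "binomial"].head(5).tolist()
        raise ValidationError(f"red-list binomials not unique: {dups}")
    mapping = rl.set_index("binomial_norm")["category"]

    out = df.copy()
    if "taxon_name_norm" not in out.columns:
        out["taxon_name_norm"] = out["taxon_name"].map(normalize_taxon)
    matched = out["taxon_name_norm"].map(mapping)
    genus_only = out["taxon_name"].map(is_genus_only)
    out["threat_status"] = matched.where(~genus_only, np.nan)
    return out


def subset_threatened(df: pd.DataFrame) -> pd.DataFrame:
    """Retain only threatened (VU/EN/CR) animal records.

    Threatened plants are excluded: the threatened-species models cover
    animals only.
    """
    keep = df["threat_status"].isin(THREATENED) & df["taxon_group"].isin(ANIMAL_GROUPS)
    return df.loc[keep].copy()
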