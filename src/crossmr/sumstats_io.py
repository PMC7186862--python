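"""Readers and writers for GWAS summary statistics, catalog associations
and LD tables.

All files are plain tab-separated text with a header row.  Source
consortia use heterogeneous column names, so every reader takes an
explicit *dialect* — a mapping from canonical field names to the column
names found in the file — with shipped presets.  Guessing effect-allele
columns silently is the dominant failure mode in this field, hence no
auto-detection.

Conventions: 1-based positions, closed intervals, alleles upper-cased,
odds ratios log-transformed to betas on read (recorded in run metadata).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for summary statistics tables.
SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "trait",
]

CATALOG_COLUMNS = ["snp_id", "chrom", "pos", "trait_label", "pvalue",
                   "study_id", "ancestry"]

#: Shipped column dialects. Keys are canonical field names, values the
#: header names in the file. ``beta`` and ``or`` are alternatives: a
#: dialect supplies one of them.
DIALECTS: dict[str, dict[str, str]] = {
    "default": {
        "snp_id": "snp_id", "chrom": "chrom", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "beta": "beta", "se": "se", "pvalue": "pvalue",
        "n": "n", "trait": "trait",
        "trait_label": "trait_label", "study_id": "study_id",
        "ancestry": "ancestry",
    },
    # Psychiatric Genomics Consortium daner-style files (binary traits).
    "pgc": {
        "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
        "effect_allele": "A1", "other_allele": "A2",
        "eaf": "FRQ_U", "or": "OR", "se": "SE", "pvalue": "P", "n": "N",
    },
    # GIANT anthropometric meta-analyses.
    "giant": {
        "snp_id": "MarkerName", "chrom": "Chr", "pos": "Pos",
        "effect_allele": "Allele1", "other_allele": "Allele2",
        "eaf": "FreqAllele1HapMapCEU", "beta": "b", "se": "se",
        "pvalue": "p", "n": "N",
    },
    # SSGAC (educational attainment / well-being) releases.
    "ssgac": {
        "snp_id": "MarkerName", "chrom": "CHR", "pos": "POS",
        "effect_allele": "A1", "other_allele": "A2",
        "eaf": "EAF", "beta": "Beta", "se": "SE", "pvalue": "Pval",
    },
    # GWAS Catalog v1.0 association download.
    "gwas_catalog": {
        "snp_id": "SNPS", "chrom": "CHR_ID", "pos": "CHR_POS",
        "trait_label": "DISEASE/TRAIT", "pvalue": "P-VALUE",
        "study_id": "STUDY ACCESSION", "ancestry": "INITIAL SAMPLE SIZE",
    },
}


class ConfigurationError(ValueError):
    """A dialect or argument problem the caller must fix."""


class InputError(ValueError):
    """Malformed or empty input data."""


@dataclass
class SummaryStatRecord:
    """One SNP's association in one phenotype's summary statistics.

    ``beta`` is the per-effect-allele estimate: trait-SD units for
    continuous traits, log-odds for binary traits (odds ratios are
    converted on read).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    trait: str = ""

    def validate(self) -> str | None:
        """Return a failure reason, or None if the record is valid."""
        if self.effect_allele not in VALID_ALLELES or \
                self.other_allele not in VALID_ALLELES:
            return "non-SNP allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive SE"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (0 < self.pvalue <= 1):
            return "p-value outside (0,1]"
        if self.pos < 1:
            return "position < 1"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "EAF outside [0,1]"
        return None


@dataclass
class CatalogAssociation:
    """A GWAS-catalog row: SNP, anthropometric trait label, P-value."""

    snp_id: str
    chrom: str
    pos: int
    trait_label: str
    pvalue: float
    study_id: str = ""
    ancestry: str = ""


@dataclass
class ExclusionLog:
    """Per-row exclusions with reasons; rows_in = rows_out + len(log)."""

    entries: list[dict] = field(default_factory=list)

    def add(self, snp_id: str, reason: str) -> None:
        self.entries.append({"snp_id": snp_id, "reason": reason})

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e["reason"]] = out.get(e["reason"], 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["snp_id", "reason"])


def _resolve_columns(df: pd.DataFrame, dialect: Mapping[str, str],
                     required: Iterable[str]) -> dict[str, str]:
    """Map canonical names to file columns, erroring on missing ones."""
    resolved = {}
    for canon in required:
        col = dialect.get(canon)
        if canon == "beta":
            # either a beta column or an OR column satisfies "beta"
            if dialect.get("beta") in df.columns:
                resolved["beta"] = dialect["beta"]
                continue
            if dialect.get("or") in df.columns:
                resolved["or"] = dialect["or"]
                continue
            raise ConfigurationError(
                "dialect provides neither a usable 'beta' nor 'or' column "
                f"(looked for {dialect.get('beta')!r} / {dialect.get('or')!r})")
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"required column {canon!r} not found "
                f"(dialect maps it to {col!r})")
        resolved[canon] = col
    # optional fields
    for canon in ("eaf", "n", "trait", "chrom", "pos"):
        if canon in resolved:
            continue
        col = dialect.get(canon)
        if col is not None and col in df.columns:
            resolved[canon] = col
    return resolved


def read_sumstats(path: str | Path,
                  dialect: str | Mapping[str, str] = "default",
                  ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Read a summary-statistics table into canonical form.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Preset name from :data:`DIALECTS` or an explicit mapping from
        canonical field names (``snp_id``, ``effect_allele``,
        ``other_allele``, ``beta`` or ``or``, ``se``, ``pvalue``, and
        optionally ``chrom``, ``pos``, ``eaf``, ``n``, ``trait``) to the
        file's column names.

    Returns
    -------
    (DataFrame, ExclusionLog)
        Validated records in :data:`SUMSTAT_COLUMNS` order and the rows
        dropped with reasons.  Odds ratios are stored as their natural
        logarithm.  Alleles are upper-cased; indels/multi-character
        alleles are rejected.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(f"unknown dialect preset {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty:
        raise InputError(f"{path}: no data rows")
    cols = _resolve_columns(
        raw, dialect,
        required=["snp_id", "effect_allele", "other_allele", "beta",
                  "se", "pvalue"])

    log = ExclusionLog()
    rows = []
    or_converted = False
    for _, r in raw.iterrows():
        snp = str(r[cols["snp_id"]]).strip()
        try:
            if "or" in cols:
                or_val = float(r[cols["or"]])
                if or_val <= 0:
                    log.add(snp, "nonpositive OR")
                    continue
                beta = math.log(or_val)
                or_converted = True
            else:
                beta = float(r[cols["beta"]])
            se = float(r[cols["se"]])
            pvalue = float(r[cols["pvalue"]])
        except (TypeError, ValueError):
            log.add(snp, "unparseable numeric field")
            continue
        eaf = None
        if "eaf" in cols and pd.notna(r[cols["eaf"]]):
            try:
                eaf = float(r[cols["eaf"]])
            except ValueError:
                eaf = None
        n = None
        if "n" in cols and pd.notna(r[cols["n"]]):
            try:
                n = int(float(r[cols["n"]]))
            except ValueError:
                n = None
        rec = SummaryStatRecord(
            snp_id=snp,
            chrom=str(r[cols["chrom"]]).strip() if "chrom" in cols else "",
            pos=int(float(r[cols["pos"]])) if "pos" in cols and pd.notna(r[cols["pos"]]) else 1,
            effect_allele=str(r[cols["effect_allele"]]).strip().upper(),
            other_allele=str(r[cols["other_allele"]]).strip().upper(),
            beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n,
            trait=str(r[cols["trait"]]) if "trait" in cols else "",
        )
        reason = rec.validate()
        if reason is not None:
            log.add(snp, reason)
            continue
        rows.append(asdict(rec))
    df = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    df.attrs["or_converted"] = or_converted
    df.attrs["source_path"] = str(path)
    return df, log


def read_catalog(path: str | Path,
                 trait_terms: list[str],
                 p_max: float = 5e-8,
                 dialect: str | Mapping[str, str] = "gwas_catalog",
                 ) -> pd.DataFrame:
    """Read catalog associations matching any trait term at P <= p_max.

    Matching is case-insensitive substring.  An empty result is returned
    with a warning, not an error (absence of hits is an answer).
    """
    import warnings

    if not trait_terms:
        raise ConfigurationError("trait_terms must be non-empty")
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(f"unknown dialect preset {dialect!r}")
    raw = pd.read_csv(Path(path), sep="\t", dtype=str)
    if raw.empty:
        raise InputError(f"{path}: no data rows")
    needed = ["snp_id", "trait_label", "pvalue"]
    cols = {}
    for canon in needed + ["chrom", "pos", "study_id", "ancestry"]:
        col = dialect.get(canon)
        if col is None or col not in raw.columns:
            if canon in needed:
                raise ConfigurationError(
                    f"required column {canon!r} not found "
                    f"(dialect maps it to {col!r})")
            continue
        cols[canon] = col

    terms = [t.lower() for t in trait_terms]
    rows = []
    for _, r in raw.iterrows():
        label = str(r[cols["trait_label"]])
        if not any(t in label.lower() for t in terms):
            continue
        try:
            p = float(r[cols["pvalue"]])
        except (TypeError, ValueError):
            continue
        if p > p_max:
            continue
        rows.append({
            "snp_id": str(r[cols["snp_id"]]).strip(),
            "chrom": str(r[cols["chrom"]]).strip() if "chrom" in cols else "",
            "pos": int(float(r[cols["pos"]])) if "pos" in cols and pd.notna(r[cols["pos"]]) else -1,
            "trait_label": label,
            "pvalue": p,
            "study_id": str(r[cols["study_id"]]) if "study_id" in cols else "",
            "ancestry": str(r[cols["ancestry"]]) if "ancestry" in cols else "",
        })
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if df.empty:
        warnings.warn(f"{path}: no rows matched trait terms {trait_terms} "
                      f"at P <= {p_max}")
    return df


class LDTable:
    """Symmetric pairwise LD lookup.

    Absent pairs return ``None`` ("unknown"), which downstream locus
    splitting treats as linked — distinct from a measured r² of zero.
    Self-pairs are 1 by definition.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float, float | None]] = ()):
        self._table: dict[frozenset, tuple[float, float | None]] = {}
        for a, b, r2, dp in pairs:
            self.add(a, b, r2, dp)

    def add(self, snp_a: str, snp_b: str, r2: float,
            d_prime: float | None = None) -> None:
        if not (0 <= r2 <= 1):
            raise InputError(f"r2 {r2} outside [0,1] for ({snp_a},{snp_b})")
        if d_prime is not None and not (0 <= d_prime <= 1):
            raise InputError(f"D' {d_prime} outside [0,1] for ({snp_a},{snp_b})")
        self._table[frozenset((snp_a, snp_b))] = (r2, d_prime)

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        if snp_a == snp_b:
            return 1.0
        got = self._table.get(frozenset((snp_a, snp_b)))
        return got[0] if got is not None else None

    def d_prime(self, snp_a: str, snp_b: str) -> float | None:
        if snp_a == snp_b:
            return 1.0
        got = self._table.get(frozenset((snp_a, snp_b)))
        return got[1] if got is not None else None

    def __len__(self) -> int:
        return len(self._table)


def read_ld_table(path: str | Path) -> LDTable:
    """Read a 4-column TSV (snp_a, snp_b, r2[, d_prime]) into an LDTable."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    for req in ("snp_a", "snp_b", "r2"):
        if req not in lower:
            raise ConfigurationError(f"LD table missing column {req!r}")
    table = LDTable()
    for _, r in df.iterrows():
        dp = None
        if "d_prime" in lower and pd.notna(r[lower["d_prime"]]):
            dp = float(r[lower["d_prime"]])
        table.add(str(r[lower["snp_a"]]).strip(), str(r[lower["snp_b"]]).strip(),
                  float(r[lower["r2"]]), dp)
    return table


def write_table(records: pd.DataFrame, path: str | Path,
                metadata: Mapping | None = None) -> None:
    """Write a canonical table as TSV with full float precision.

    A JSON run-metadata sidecar (``<path>.meta.json``) records the
    package version plus any caller-supplied entries (input paths,
    thresholds, seeds), so every output is traceable to its run.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")
    from crossmr import __version__
    meta = {"package_version": __version__, "output": str(path)}
    if metadata:
        meta.update(metadata)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=SUMSTAT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        eaf = d.get("eaf")
        n = d.get("n")
        recs.append(SummaryStatRecord(
            snp_id=d["snp_id"], chrom=str(d["chrom"]), pos=int(d["pos"]),
            effect_allele=d["effect_allele"], other_allele=d["other_allele"],
            beta=float(d["beta"]), se=float(d["se"]), pvalue=float(d["pvalue"]),
            eaf=None if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)) else float(eaf),
            n=None if n is None or (isinstance(n, float) and np.isnan(n)) else int(n),
            trait=str(d.get("trait", "")),
        ))
    return recs
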