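"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires the outcome effect of each SNP to be expressed
per copy of the *same* allele as the exposure effect.  Studies report
alleles on arbitrary strands and in arbitrary effect/other order, so a
pair of records can match directly, after swapping alleles (negate the
outcome beta), or after complementing the outcome strand.  Palindromic
SNPs (A/T or C/G) cannot be strand-resolved from alleles alone: the
default *strict* mode drops them; an *eaf-infer* mode keeps those whose
effect-allele frequency is decisive (outside [0.42, 0.58]) in both
studies and uses frequency agreement to resolve the strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from crossmr.sumstats_io import (
    SummaryStatRecord, ExclusionLog, VALID_ALLELES,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: EAF band in which a palindromic SNP's strand cannot be inferred.
EAF_AMBIGUOUS_BAND = (0.42, 0.58)

INSTRUMENT_COLUMNS = [
    "snp_id", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "flipped", "palindromic",
]


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizedInstrument:
    """One SNP with exposure and outcome effects on a common allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flipped: bool = False       # outcome beta negated during alignment
    palindromic: bool = False


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    a1, a2 = a1.upper(), a2.upper()
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"non-nucleotide allele in ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _eaf_decisive(eaf: float | None) -> bool:
    lo, hi = EAF_AMBIGUOUS_BAND
    return eaf is not None and not (lo <= eaf <= hi)


def harmonize_pair(exp: SummaryStatRecord, out: SummaryStatRecord,
                   mode: Literal["strict", "eaf-infer"] = "strict",
                   ) -> HarmonizedInstrument | tuple[None, str]:
    """Align one outcome record to the exposure's effect allele.

    Returns a :class:`HarmonizedInstrument`, or ``(None, reason)`` when
    the SNP must be excluded (palindromic in strict mode, irreconcilable
    alleles, or indecisive frequencies in eaf-infer mode).
    """
    if exp.snp_id != out.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    ea_x, oa_x = exp.effect_allele.upper(), exp.other_allele.upper()
    ea_y, oa_y = out.effect_allele.upper(), out.other_allele.upper()
    palindromic = is_palindromic(ea_x, oa_x)

    if palindromic:
        if mode == "strict":
            return None, "palindromic"
        # eaf-infer: need decisive, consistent frequencies in both studies
        if not (_eaf_decisive(exp.eaf) and _eaf_decisive(out.eaf)):
            return None, "palindromic (EAF indecisive)"
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, "ambiguous"
        # For a palindromic pair, allele labels cannot distinguish
        # strands; only frequency agreement identifies the allele: the
        # outcome's effect allele is the exposure's iff both EAFs fall
        # on the same side of 0.5.
        keep = (out.eaf > 0.5) == (exp.eaf > 0.5)
        if keep:
            return HarmonizedInstrument(
                snp_id=exp.snp_id, effect_allele=ea_x, other_allele=oa_x,
                beta_exp=exp.beta, se_exp=exp.se,
                beta_out=out.beta, se_out=out.se,
                eaf_exp=exp.eaf, eaf_out=out.eaf,
                flipped=False, palindromic=True)
        return HarmonizedInstrument(
            snp_id=exp.snp_id, effect_allele=ea_x, other_allele=oa_x,
            beta_exp=exp.beta, se_exp=exp.se,
            beta_out=-out.beta, se_out=out.se,
            eaf_exp=exp.eaf, eaf_out=1 - out.eaf,
            flipped=True, palindromic=True)

    def build(beta_out: float, eaf_out: float | None, flipped: bool):
        return HarmonizedInstrument(
            snp_id=exp.snp_id, effect_allele=ea_x, other_allele=oa_x,
            beta_exp=exp.beta, se_exp=exp.se,
            beta_out=beta_out, se_out=out.se,
            eaf_exp=exp.eaf, eaf_out=eaf_out,
            flipped=flipped, palindromic=False)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return build(out.beta, out.eaf, False)
    if (ea_y, oa_y) == (oa_x, ea_x):
        return build(-out.beta, None if out.eaf is None else 1 - out.eaf, True)
    # strand complement
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return build(out.beta, out.eaf, False)
    if (cea, coa) == (oa_x, ea_x):
        return build(-out.beta, None if out.eaf is None else 1 - out.eaf, True)
    return None, "ambiguous"


def _iter_records(table: pd.DataFrame | Iterable[SummaryStatRecord]):
    if isinstance(table, pd.DataFrame):
        from crossmr.sumstats_io import frame_to_records
        return frame_to_records(table)
    return list(table)


def harmonize_datasets(exposure: pd.DataFrame | Iterable[SummaryStatRecord],
                       outcome: pd.DataFrame | Iterable[SummaryStatRecord],
                       mode: Literal["strict", "eaf-infer"] = "strict",
                       ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Inner-join exposure and outcome on snp_id and harmonize each SNP.

    Returns the instrument table plus an exclusion log covering
    palindromic, ambiguous and absent-from-outcome SNPs.  Raises if no
    instrument survives ("no usable instruments").
    """
    exp_records = _iter_records(exposure)
    out_by_id = {r.snp_id: r for r in _iter_records(outcome)}
    log = ExclusionLog()
    instruments: list[HarmonizedInstrument] = []
    for exp in exp_records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            log.add(exp.snp_id, "absent from outcome")
            continue
        result = harmonize_pair(exp, out, mode=mode)
        if isinstance(result, HarmonizedInstrument):
            instruments.append(result)
        else:
            log.add(exp.snp_id, result[1])
    if not instruments:
        raise HarmonizationError("no usable instruments")
    df = pd.DataFrame(
        [{c: getattr(i, c) for c in INSTRUMENT_COLUMNS} for i in instruments],
        columns=INSTRUMENT_COLUMNS)
    return df, log
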