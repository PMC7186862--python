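"""Cross-trait look-up pipeline.

Genome-wide-significant anthropometric SNPs are clustered into
independent loci (positional window around a running midpoint, then
splitting on demonstrated pairwise linkage equilibrium), looked up in
mental-phenotype summary statistics against a Bonferroni threshold,
reduced to one lead SNP per locus, and tabulated for effect-direction
concordance between the anthropometric and mental traits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from crossmr.sumstats_io import LDTable, ExclusionLog
from crossmr.harmonize import harmonize_pair
from crossmr.sumstats_io import frame_to_records

logger = logging.getLogger(__name__)

#: Trait-label substrings treated as overall-adiposity (BMI stratum)
#: rather than adjusted body-fat-distribution measures.
BMI_TERMS = ("body mass index", "bmi", "obesity")


@dataclass
class Locus:
    """A clustered genomic interval of associated SNPs.

    Bounds are the extreme member positions (closed interval, 1-based).
    ``lead_snp`` is set by :func:`select_lead_snp`.
    """

    locus_id: int
    chrom: str
    start: int
    end: int
    members: list[str]
    lead_snp: str | None = None
    anthro_traits: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class LookupHit:
    snp_id: str
    phenotype: str
    pvalue: float
    beta: float
    significant: bool


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests controlling the family-wise
    error rate over n_tests look-ups."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_threshold(threshold: float) -> str:
    """Display form at 3 significant figures, e.g. '4.98e-05'."""
    return f"{threshold:.2e}"


def _catalog_tuples(snps) -> list[tuple[str, str, int, str]]:
    """Normalize catalog input to (snp_id, chrom, pos, trait_label)."""
    if isinstance(snps, pd.DataFrame):
        return [(str(r.snp_id), str(r.chrom), int(r.pos), str(r.trait_label))
                for r in snps.itertuples(index=False)]
    out = []
    for s in snps:
        out.append((s.snp_id, s.chrom, s.pos, s.trait_label))
    return out


def define_loci(snps, window_kb: float = 500.0,
                ld: LDTable | None = None,
                r2_max: float = 0.01, dprime_max: float = 0.01,
                ) -> tuple[list[Locus], ExclusionLog]:
    """Partition catalog SNPs into independent loci.

    Within a chromosome, SNPs sorted by position are greedily merged
    while each candidate lies within ``window_kb`` of the running
    positional midpoint of the current cluster (midpoint recomputed
    after every merge).  Within a positional cluster, a SNP pair with
    *known* r² < ``r2_max`` and D′ < ``dprime_max`` is in linkage
    equilibrium; single-linkage over the complement relation (pairs
    linked unless demonstrably in equilibrium; unknown LD counts as
    linked) splits the cluster into independent loci.  Loci are numbered
    consecutively in genomic order.

    Duplicate SNP ids contribute one member each; SNPs without a
    position are excluded with a logged reason.
    """
    log = ExclusionLog()
    tuples = _catalog_tuples(snps)
    # collapse duplicate (snp_id) rows, pooling trait labels
    by_snp: dict[str, dict] = {}
    for snp_id, chrom, pos, trait in tuples:
        if pos is None or (isinstance(pos, float) and math.isnan(pos)) or pos < 1:
            log.add(snp_id, "missing position")
            continue
        if snp_id in by_snp:
            by_snp[snp_id]["traits"].add(trait)
        else:
            by_snp[snp_id] = {"chrom": chrom, "pos": int(pos),
                              "traits": {trait}}

    half_window = window_kb * 1000.0
    clusters: list[list[str]] = []
    for chrom in sorted({v["chrom"] for v in by_snp.values()},
                        key=_chrom_sort_key):
        ids = sorted((s for s, v in by_snp.items() if v["chrom"] == chrom),
                     key=lambda s: (by_snp[s]["pos"], s))
        current: list[str] = []
        for snp in ids:
            pos = by_snp[snp]["pos"]
            if current:
                mid = (by_snp[current[0]]["pos"]
                       + by_snp[current[-1]]["pos"]) / 2.0
                if abs(pos - mid) <= half_window:
                    current.append(snp)
                    continue
                clusters.append(current)
            current = [snp]
        if current:
            clusters.append(current)

    # LD-based splitting: single linkage over "linked" relation
    loci: list[Locus] = []
    for cluster in clusters:
        for component in _split_by_ld(cluster, ld, r2_max, dprime_max):
            poss = [by_snp[s]["pos"] for s in component]
            traits = set()
            for s in component:
                traits |= by_snp[s]["traits"]
            loc = Locus(locus_id=-1, chrom=by_snp[component[0]]["chrom"],
                        start=min(poss), end=max(poss),
                        members=sorted(component,
                                       key=lambda s: (by_snp[s]["pos"], s)),
                        anthro_traits=traits)
            if loc.span > 1_000_000:
                logger.info("locus on chr%s spans %.2f Mb (> 1 Mb)",
                            loc.chrom, loc.span / 1e6)
            loci.append(loc)
    loci.sort(key=lambda l: (_chrom_sort_key(l.chrom), l.start, l.end))
    for i, loc in enumerate(loci, start=1):
        loc.locus_id = i
    return loci, log


def _chrom_sort_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    try:
        return (0, int(c))
    except ValueError:
        return (1, c)


def _split_by_ld(cluster: list[str], ld: LDTable | None,
                 r2_max: float, dprime_max: float) -> list[list[str]]:
    """Connected components of the 'linked' relation: a pair is
    unlinked only when both r² and D′ are known and below threshold."""
    if ld is None or len(cluster) == 1:
        return [cluster]
    parent = {s: s for s in cluster}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, a in enumerate(cluster):
        for b in cluster[i + 1:]:
            r2 = ld.r2(a, b)
            dp = ld.d_prime(a, b)
            in_equilibrium = (r2 is not None and dp is not None
                             and r2 < r2_max and dp < dprime_max)
            if not in_equilibrium:
                union(a, b)
    comps: dict[str, list[str]] = {}
    for s in cluster:
        comps.setdefault(find(s), []).append(s)
    # preserve positional order of the cluster
    order = {s: i for i, s in enumerate(cluster)}
    return sorted((sorted(c, key=order.get) for c in comps.values()),
                  key=lambda c: order[c[0]])


def crosstrait_lookup(snps, phenotype_tables: Mapping[str, pd.DataFrame],
                      threshold: float,
                      anthro_stats: pd.DataFrame | None = None,
                      ) -> tuple[list[LookupHit], pd.DataFrame]:
    """Look up catalog SNPs in each phenotype's summary statistics.

    Returns hits (one per SNP × phenotype where the SNP is present) and
    a coverage report of absences.  When ``anthro_stats`` is supplied,
    each hit's beta is sign-aligned to the anthropometric effect allele
    via the harmonization rules; proxies are never substituted.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0,1)")
    ids = [t[0] for t in _catalog_tuples(snps)]
    seen = set()
    ids = [s for s in ids if not (s in seen or seen.add(s))]

    anthro_by_id = {}
    if anthro_stats is not None:
        anthro_by_id = {r.snp_id: r for r in frame_to_records(anthro_stats)}

    hits: list[LookupHit] = []
    coverage_rows = []
    for pheno, table in phenotype_tables.items():
        recs = {r.snp_id: r for r in frame_to_records(table)}
        for snp in ids:
            rec = recs.get(snp)
            if rec is None:
                coverage_rows.append({"snp_id": snp, "phenotype": pheno,
                                      "present": False})
                continue
            beta = rec.beta
            if snp in anthro_by_id:
                harmonized = harmonize_pair(anthro_by_id[snp], rec,
                                            mode="strict")
                if not isinstance(harmonized, tuple):
                    beta = harmonized.beta_out
            coverage_rows.append({"snp_id": snp, "phenotype": pheno,
                                  "present": True})
            hits.append(LookupHit(snp_id=snp, phenotype=pheno,
                                  pvalue=rec.pvalue, beta=beta,
                                  significant=rec.pvalue < threshold))
    coverage = pd.DataFrame(coverage_rows,
                            columns=["snp_id", "phenotype", "present"])
    return hits, coverage


def select_lead_snp(locus: Locus, hits: Iterable[LookupHit]) -> str:
    """Choose the locus representative: (1) most phenotypes with a
    significant hit, (2) lowest significant P-value, (3) rsID order
    (a deterministic final tie-break, logged when it decides)."""
    if not locus.members:
        raise ValueError("locus has no members")
    members = set(locus.members)
    sig: dict[str, list[LookupHit]] = {m: [] for m in locus.members}
    for h in hits:
        if h.significant and h.snp_id in members:
            sig[h.snp_id].append(h)

    def key(snp: str):
        n_pheno = len({h.phenotype for h in sig[snp]})
        min_p = min((h.pvalue for h in sig[snp]), default=math.inf)
        return (-n_pheno, min_p, snp)

    ranked = sorted(locus.members, key=key)
    if len(ranked) > 1 and key(ranked[0])[:2] == key(ranked[1])[:2]:
        logger.info("locus %s: lead SNP tie broken by rsID order (%s)",
                    locus.locus_id, ranked[0])
    locus.lead_snp = ranked[0]
    return ranked[0]


def direction_concordance(loci: Sequence[Locus], hits: Iterable[LookupHit],
                          anthro_stats: pd.DataFrame,
                          mental_stats: Mapping[str, pd.DataFrame],
                          bmi_terms: Sequence[str] = BMI_TERMS,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect-direction concordance per locus × phenotype.

    For each significant hit at a locus lead SNP, both effects are
    aligned to the anthropometric-trait-increasing allele; a hit is
    concordant when the mental-phenotype beta then has the same sign as
    the (positive) anthropometric beta.  Loci are stratified into a BMI
    stratum (any member trait label matching ``bmi_terms``) and an
    adjusted-only stratum.  Returns (entries, counts) where counts is
    phenotype × stratum × {concordant, discordant}.  Zero betas are
    flagged indeterminate and excluded from counts.
    """
    anthro_by_id = {r.snp_id: r for r in frame_to_records(anthro_stats)}
    mental_by_pheno = {p: {r.snp_id: r for r in frame_to_records(t)}
                       for p, t in mental_stats.items()}
    sig_hits = [h for h in hits if h.significant]
    hit_index: dict[tuple[str, str], LookupHit] = {
        (h.snp_id, h.phenotype): h for h in sig_hits}

    entries = []
    for locus in loci:
        snp = locus.lead_snp or locus.members[0]
        anthro = anthro_by_id.get(snp)
        if anthro is None:
            continue
        stratum = "bmi" if any(
            any(term in t.lower() for term in bmi_terms)
            for t in locus.anthro_traits) else "adjusted_only"
        for pheno, table in mental_by_pheno.items():
            if (snp, pheno) not in hit_index:
                continue
            mental = table.get(snp)
            if mental is None:
                continue
            harmonized = harmonize_pair(anthro, mental, mode="strict")
            if isinstance(harmonized, tuple):
                continue
            # orient to the anthropometric-trait-increasing allele
            beta_anthro = harmonized.beta_exp
            beta_mental = harmonized.beta_out
            if beta_anthro < 0:
                beta_anthro, beta_mental = -beta_anthro, -beta_mental
            if beta_mental == 0 or beta_anthro == 0:
                logger.info("locus %s / %s: zero beta, direction "
                            "indeterminate", locus.locus_id, pheno)
                entries.append({"locus_id": locus.locus_id,
                                "phenotype": pheno, "stratum": stratum,
                                "concordant": None})
                continue
            entries.append({"locus_id": locus.locus_id, "phenotype": pheno,
                            "stratum": stratum,
                            "concordant": beta_mental > 0})
    entries_df = pd.DataFrame(
        entries, columns=["locus_id", "phenotype", "stratum", "concordant"])
    counted = entries_df.dropna(subset=["concordant"])
    if counted.empty:
        counts = pd.DataFrame(
            columns=["phenotype", "stratum", "concordant", "discordant"])
    else:
        counts = (counted.groupby(["phenotype", "stratum"])["concordant"]
                  .agg(concordant=lambda s: int(s.sum()),
                       discordant=lambda s: int((~s.astype(bool)).sum()))
                  .reset_index())
    return entries_df, counts


def confirmatory_lookup(prior_hits: Iterable[LookupHit],
                        independent_table: pd.DataFrame,
                        threshold: float,
                        locus_of: Mapping[str, int] | None = None,
                        discovery_path: str | None = None,
                        independent_path: str | None = None,
                        ) -> dict:
    """Replication of prior significant hits in an independent dataset.

    A hit replicates when its SNP is present below the same threshold;
    absent SNPs are 'not assessable', never failures.  Counts are given
    at SNP level and, when a SNP→locus mapping is supplied, locus level.
    """
    if discovery_path is not None and independent_path is not None \
            and str(discovery_path) == str(independent_path):
        raise ValueError("independent table must differ from discovery table")
    recs = {r.snp_id: r for r in frame_to_records(independent_table)}
    snps = sorted({h.snp_id for h in prior_hits if h.significant})
    replicated, failed, absent = [], [], []
    for snp in snps:
        rec = recs.get(snp)
        if rec is None:
            absent.append(snp)
        elif rec.pvalue < threshold:
            replicated.append(snp)
        else:
            failed.append(snp)
    report = {
        "n_prior": len(snps),
        "n_replicated": len(replicated),
        "n_failed": len(failed),
        "n_not_assessable": len(absent),
        "replicated": replicated,
        "failed": failed,
        "not_assessable": absent,
        "discovery_path": discovery_path,
        "independent_path": independent_path,
        "threshold": threshold,
    }
    if locus_of is not None:
        loci_prior = {locus_of[s] for s in snps if s in locus_of}
        loci_rep = {locus_of[s] for s in replicated if s in locus_of}
        report["n_loci_prior"] = len(loci_prior)
        report["n_loci_replicated"] = len(loci_rep)
    return report
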