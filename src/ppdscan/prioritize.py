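"""Evidence integration and candidate ranking.

The combining logic is deliberate and qualitative: each candidate gene (or
unannotated region) is flagged for every evidence track whose passing
regions overlap it — XP-EHH regions, SNP F_ST windows, INDEL F_ST windows —
and annotated with its best association p-value and its count of
segregation-concordant variants. Candidates are ranked by evidence-flag
count (descending), then best association p (ascending), then coordinates;
the ranking is a deterministic pure function of its inputs. Variants that
are both concordant under the chosen inheritance model and annotated as
nonsynonymous coding changes are highlighted as putatively causal.

The evidence-count composite is this package's formalization of
replication-across-tracks reasoning; output headers label it as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import GeneModel

__all__ = ["EvidenceTable", "CandidateReport", "integrate_evidence", "rank_candidates"]

EVIDENCE_TRACKS = ("xpehh_region", "fst_snp_window", "fst_indel_window", "assoc_top")


@dataclass
class EvidenceTable:
    """Per-candidate ledger; ``table`` columns: candidate, chrom, start, end,
    is_gene, xpehh_region, fst_snp_window, fst_indel_window, n_flags,
    best_assoc_p, n_concordant, has_nonsynonymous, classes_present."""

    table: pd.DataFrame
    variants: pd.DataFrame  # per-variant audit rows with candidate assignment


@dataclass
class CandidateReport:
    ranked: pd.DataFrame
    top_variants: pd.DataFrame
    causal_flagged: pd.DataFrame  # concordant + nonsynonymous variants


def _overlaps(start: int, end: int, regions: Sequence[tuple[str, int, int]], chrom: str) -> bool:
    return any(c == chrom and s <= end and e >= start for c, s, e in regions)


def integrate_evidence(
    xpehh_regions: Sequence[tuple[str, int, int]],
    fst_snp_regions: Sequence[tuple[str, int, int]],
    fst_indel_regions: Sequence[tuple[str, int, int]],
    assoc: pd.DataFrame,
    concordance: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_model: GeneModel,
    flank_bp: int = 0,
    top_k_assoc: int = 10,
) -> EvidenceTable:
    """Intersect the evidence tracks with genes (plus unannotated regions).

    ``assoc`` is an ``association_scan`` table, ``concordance`` a
    ``concordance_scan`` table and ``annotations`` an ``annotation_table``.
    Candidates are every gene in the model plus every evidence region that
    overlaps no gene (reported as region candidates). Gene assignment uses
    interval overlap with a configurable flank (default 0 bp).
    """
    chroms_evidence = {c for c, _, _ in (*xpehh_regions, *fst_snp_regions, *fst_indel_regions)}
    chroms_genes = {g.chrom for g in gene_model.genes}
    if chroms_evidence and chroms_genes and not (chroms_evidence & chroms_genes):
        raise ValueError(
            "chromosome names of evidence tracks and gene model are disjoint; "
            "inputs appear to use different coordinate systems"
        )

    candidates: list[dict] = []
    for g in gene_model.genes:
        lo, hi = g.span
        candidates.append(
            {"candidate": g.id, "chrom": g.chrom, "start": lo - flank_bp,
             "end": hi + flank_bp, "is_gene": True}
        )

    def gene_free(regions: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
        out = []
        for c, s, e in regions:
            if not any(g.chrom == c and g.span[0] - flank_bp <= e and g.span[1] + flank_bp >= s
                       for g in gene_model.genes):
                out.append((c, s, e))
        return out

    seen: set[tuple[str, int, int]] = set()
    for c, s, e in (*gene_free(xpehh_regions), *gene_free(fst_snp_regions),
                    *gene_free(fst_indel_regions)):
        if (c, s, e) not in seen:
            seen.add((c, s, e))
            candidates.append(
                {"candidate": f"IGR:{c}:{s}-{e}", "chrom": c, "start": s, "end": e,
                 "is_gene": False}
            )

    # tolerate empty inputs (the empty-table case must flow through cleanly)
    if assoc.empty:
        assoc = pd.DataFrame(columns=["CHR", "SNP", "BP", "A1", "F_A", "F_U", "A2",
                                      "CHISQ", "P"])
    if concordance.empty:
        concordance = pd.DataFrame(columns=["CHROM", "POS", "MODEL", "CONCORDANT"])
    if annotations.empty:
        annotations = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "class",
                                            "gene", "aa_change"])
    ann = annotations.copy()
    merged = assoc.merge(
        concordance[["CHROM", "POS", "CONCORDANT"]],
        left_on=["CHR", "BP"], right_on=["CHROM", "POS"], how="left",
    ).merge(
        ann[["chrom", "pos", "class", "aa_change"]],
        left_on=["CHR", "BP"], right_on=["chrom", "pos"], how="left",
    )
    merged["CONCORDANT"] = merged["CONCORDANT"].fillna(0).astype(int)
    merged["class"] = merged["class"].fillna("unknown")
    # a candidate containing one of the genome-wide top-k association hits
    # carries the fourth evidence flag (the association track)
    if len(merged):
        top_hits = merged.nsmallest(top_k_assoc, "P")[["CHR", "BP"]]
        top_set = set(zip(top_hits["CHR"], top_hits["BP"]))
    else:
        top_set = set()

    rows = []
    variant_rows = []
    for cand in candidates:
        c, s, e = cand["chrom"], cand["start"], cand["end"]
        cand["xpehh_region"] = int(_overlaps(s, e, xpehh_regions, c))
        cand["fst_snp_window"] = int(_overlaps(s, e, fst_snp_regions, c))
        cand["fst_indel_window"] = int(_overlaps(s, e, fst_indel_regions, c))
        sub = merged[(merged["CHR"] == c) & (merged["BP"] >= s) & (merged["BP"] <= e)]
        cand["assoc_top"] = int(any((c, bp) in top_set for bp in sub["BP"]))
        cand["n_flags"] = (cand["xpehh_region"] + cand["fst_snp_window"]
                           + cand["fst_indel_window"] + cand["assoc_top"])
        cand["best_assoc_p"] = float(sub["P"].min()) if len(sub) else float("nan")
        cand["n_concordant"] = int(sub["CONCORDANT"].sum()) if len(sub) else 0
        cand["has_nonsynonymous"] = bool((sub["class"] == "CDS_nonsynonymous").any())
        cand["classes_present"] = ",".join(sorted(set(sub["class"]) - {"unknown"})) or "."
        rows.append(cand)
        if len(sub):
            v = sub.copy()
            v.insert(0, "candidate", cand["candidate"])
            variant_rows.append(v)
    table = pd.DataFrame(rows)
    variants = (
        pd.concat(variant_rows, ignore_index=True)
        if variant_rows
        else pd.DataFrame(columns=["candidate", "CHR", "BP", "P", "CONCORDANT", "class"])
    )
    return EvidenceTable(table=table, variants=variants)


def rank_candidates(evidence: EvidenceTable, top_k_assoc: int = 10) -> CandidateReport:
    """Rank candidates and highlight putatively causal variants.

    Sort order: evidence-flag count (desc), best association p (asc; NaN
    last), chromosome, start. Within each candidate, variants are ranked by
    p; the report keeps the top ``top_k_assoc``. A variant is flagged
    putatively causal iff it is concordant under the chosen model AND
    annotated CDS_nonsynonymous — candidates whose best variant fails
    concordance stay in the ranking but receive no causal flag.
    """
    tab = evidence.table.copy()
    if tab.empty:
        empty = pd.DataFrame()
        return CandidateReport(tab, empty, empty)
    tab["_p"] = tab["best_assoc_p"].fillna(np.inf)
    tab = tab.sort_values(
        by=["n_flags", "_p", "chrom", "start"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns="_p")
    tab.insert(0, "rank", range(1, len(tab) + 1))
    tab = tab.reset_index(drop=True)

    var = evidence.variants.copy()
    if len(var):
        var = var.sort_values(by=["P", "CHR", "BP"], kind="mergesort")
        top = var.drop_duplicates(subset=["CHR", "BP"]).head(top_k_assoc).copy()
        causal = var[(var["CONCORDANT"] == 1) & (var["class"] == "CDS_nonsynonymous")].copy()
    else:
        top = var
        causal = var
    return CandidateReport(ranked=tab, top_variants=top, causal_flagged=causal)
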