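"""Independent brute-force oracles used by the test suite.

Each oracle is written from the rule definition directly (per-base
enumeration, literal triple loops, explicit running sums, full
hypergeometric enumeration) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_region(site, gene, window: int = 3000) -> str:
    """Per-base enumeration of the site-region label with the documented
    precedence (promoter bins > 3'UTR > CDS > exon > intron > distal)."""
    if site.interval.chrom != gene.chrom:
        return "distal"
    bases = range(site.interval.start, site.interval.end)
    tss = gene.tss
    prom_bases = [b for b in bases if tss - window <= b < tss + window]
    if prom_bases:
        d = min(abs(b - tss) for b in bases)
        if d < window // 3:
            return "promoter_lt1kb"
        if d < 2 * (window // 3):
            return "promoter_1to2kb"
        return "promoter_2to3kb"

    def _in_any(ivs):
        return any(iv.start <= b < iv.end for b in bases for iv in ivs)

    if _in_any(gene.utr3):
        return "utr3"
    if _in_any(gene.cds):
        return "cds"
    if _in_any(gene.exons):
        return "exon"
    if any(gene.body.start <= b < gene.body.end for b in bases):
        return "intron"
    return "distal"


def ssgsea_running_sum(values, gene_ids, gene_set, alpha: float) -> float:
    """Explicit step-by-step running-sum single-sample enrichment score."""
    pairs = sorted(zip(values, gene_ids), key=lambda t: (-t[0], t[1]))
    n = len(pairs)
    members = [g in gene_set for _v, g in pairs]
    n_in = sum(members)
    weights = []
    for r, (_v, _g) in enumerate(pairs, start=1):
        rank_norm = (n - r + 1) / n
        weights.append(abs(rank_norm) ** alpha)
    total_in = sum(w for w, m in zip(weights, members) if m)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for w, m in zip(weights, members):
        if m:
            cum_in += w / total_in
        else:
            cum_out += 1.0 / (n - n_in)
        score += cum_in - cum_out
    return score


def fisher_two_sided_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided conditional exact p by full enumeration over tables with
    the observed margins (hypergeometric; tie guard on the observed pmf)."""
    n = n11 + n10 + n01 + n00
    r, c = n11 + n10, n11 + n01
    lo, hi = max(0, r + c - n), min(r, c)
    pmfs = {x: sps.hypergeom.pmf(x, n, r, c) for x in range(lo, hi + 1)}
    obs = pmfs[n11]
    return min(1.0, sum(p for p in pmfs.values() if p <= obs * (1 + 1e-7)))


def emrg1_triple_loop(dhms, deg, genes, window: int = 3000) -> set[tuple[str, str]]:
    """Literal application of criterion 1: for every (gene, cell line, site)
    check the promoter overlap and direction concordance.  Returns the
    (gene_id, mod_type) support set."""
    out = set()
    for gene in genes:
        for cell_line in dhms:
            if cell_line not in deg:
                continue
            recs = [
                r
                for r in deg[cell_line]
                if r.gene_id == gene.gene_id and abs(r.log2fc) > 1 and r.p_value < 0.05
            ]
            for site in dhms[cell_line]:
                if site.mod_type == "m6A":
                    continue
                if not (abs(site.fold_change) > 1 and site.p_value < 0.05):
                    continue
                if site.interval.chrom != gene.chrom:
                    continue
                w_lo, w_hi = gene.tss - window, gene.tss + window
                if not (site.interval.start < w_hi and w_lo < site.interval.end):
                    continue
                for rec in recs:
                    if (site.fold_change > 0) == (rec.log2fc > 0):
                        out.add((gene.gene_id, site.mod_type))
    return out


def emrg2_triple_loop(
    mms, ceg, genes, writers_readers, erasers, window: int = 3000
) -> set[str]:
    """Literal application of criterion 2.  Returns the supported gene set."""
    out = set()
    for gene in genes:
        has_corr = False
        for rec in ceg:
            if rec.gene_id != gene.gene_id or rec.p_adj >= 0.05:
                continue
            if rec.regulator_id in writers_readers and rec.rho > 0.3:
                has_corr = True
            if rec.regulator_id in erasers and rec.rho < -0.3:
                has_corr = True
        if not has_corr:
            continue
        for cell_line in mms:
            for site in mms[cell_line]:
                if site.mod_type != "m6A":
                    continue
                if not (abs(site.fold_change) > 1 and site.p_value < 0.05):
                    continue
                if site.interval.chrom != gene.chrom:
                    continue
                regions = list(gene.exons) + [
                    type(gene.body)(
                        gene.chrom,
                        max(0, gene.tss - window),
                        gene.tss + window,
                        gene.strand,
                    )
                ]
                if any(
                    site.interval.start < iv.end and iv.start < site.interval.end
                    for iv in regions
                ):
                    out.add(gene.gene_id)
    return out


def logrank_by_hand(times, events, groups):
    """Observed-minus-expected log-rank statistic by explicit enumeration
    over event times (two groups)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    gvals = np.unique(groups)
    assert len(gvals) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == gvals[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == gvals[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2
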