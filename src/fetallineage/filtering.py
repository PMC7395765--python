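"""Clone-vs-bulk somatic variant filtering.

Reduces raw joint calls to (a) the clonal somatic SNV / indel set of each
clonally expanded cell and (b) the shared-variant table (variants
confidently present in >=1 clone and confidently absent in >=1 clone, with
their bulk VAFs).  The filter cascade is applied in a fixed order so that
per-stage attrition is reportable:

    caller PASS -> QUAL -> MQ -> single ALT -> exclusion list (rescuable by
    ID) -> clone quality (GQ/VAF/DP) -> bulk quality (GQ/VAF=0/DP) ->
    clonality VAF cut (0.3 autosomal; 0.2 on the trisomic contig of T21
    clones; the male-X hemizygous rule).

"VAF = 0" in the bulk is interpreted strictly as zero alternate reads.
Clone clonality is additionally checked with a two-component beta-binomial
mixture fitted by EM (the pass rule is a minimum weight on the clonal
component near VAF 0.5).
"""
from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .variant_io import SampleCall, SampleMeta, VariantRecord


@dataclass
class FilterConfig:
    snv_qual_min: float = 50.0
    mq_min: float = 60.0
    clone_gq_min: float = 99.0
    clone_vaf_min: float = 0.1       # strict: VAF must exceed this
    bulk_gq_min: float = 10.0
    bulk_vaf_max: float = 0.0        # zero alt reads
    dp_min: int = 20
    clonal_vaf_min: float = 0.3
    clonal_vaf_min_tri21: float = 0.2
    male_x_vaf_min: float = 0.99
    male_x_gq_min: float = 10.0
    male_x_dp_min: int = 10
    indel_qual_min: float = 250.0
    indel_gq_min: float = 99.0
    germline_indel_flank_bp: int = 100
    clonality_pass_weight: float = 0.7
    trisomy_contig: str = "chr21"
    x_contig: str = "chrX"
    missing_mq_fails: bool = True    # conservative default
    allowed_contigs: tuple | None = None  # None = autosomes + X (everything given)

    def __post_init__(self):
        if not (0 < self.clonal_vaf_min_tri21 < self.clonal_vaf_min):
            raise ValueError("clonal_vaf_min_tri21 must lie below clonal_vaf_min")
        if not (0 < self.clonality_pass_weight <= 1):
            raise ValueError("clonality_pass_weight must be in (0, 1]")


STAGES = ("candidate", "caller_pass", "qual", "mq", "multiallelic",
          "exclusion_list", "clone_quality", "bulk_quality", "clonality_vaf")


@dataclass
class ClonalFilterResult:
    retained: list
    attrition: "OrderedDict[str, int]"   # stage -> records removed at stage


def _meta_by_sample(meta) -> dict:
    return {m.sample_id: m for m in meta}


def _site_gates(rec: VariantRecord, cfg: FilterConfig, qual_min,
                exclusion, rescue_ids) -> str | None:
    """Return the name of the first failing site-level gate, else None."""
    if not rec.filter_pass:
        return "caller_pass"
    if rec.qual is None or rec.qual < qual_min:
        return "qual"
    if rec.mq is None:
        if cfg.missing_mq_fails:
            return "mq"
    elif rec.mq < cfg.mq_min:
        return "mq"
    if rec.multiallelic:
        return "multiallelic"
    if exclusion and rec.key in exclusion:
        if not (rescue_ids and set(rec.ids) & rescue_ids):
            return "exclusion_list"
    return None


def _is_male_x(rec: VariantRecord, clone_meta: SampleMeta, cfg: FilterConfig) -> bool:
    return rec.contig == cfg.x_contig and clone_meta.sex == "M"


def _clone_quality_ok(call: SampleCall, male_x: bool, cfg: FilterConfig,
                      gq_min=None) -> bool:
    gq_min = (cfg.male_x_gq_min if male_x else cfg.clone_gq_min) if gq_min is None else gq_min
    dp_min = cfg.male_x_dp_min if male_x else cfg.dp_min
    vaf = call.vaf
    return (call.gq is not None and call.gq >= gq_min
            and call.dp is not None and call.dp >= dp_min
            and vaf is not None and vaf > cfg.clone_vaf_min)


def _bulk_quality_ok(call: SampleCall, male_x: bool, cfg: FilterConfig,
                     gq_min=None) -> bool:
    gq_min = cfg.bulk_gq_min if gq_min is None else gq_min
    dp_min = cfg.male_x_dp_min if male_x else cfg.dp_min
    return (call.gq is not None and call.gq >= gq_min
            and call.dp is not None and call.dp >= dp_min
            and call.ad_alt == 0)


def _clonality_ok(rec: VariantRecord, call: SampleCall, male_x: bool,
                  clone_meta: SampleMeta, cfg: FilterConfig) -> bool:
    vaf = call.vaf
    if vaf is None:
        return False
    if male_x:
        return vaf >= cfg.male_x_vaf_min
    if clone_meta.trisomy21 and rec.contig == cfg.trisomy_contig:
        return vaf >= cfg.clonal_vaf_min_tri21
    return vaf >= cfg.clonal_vaf_min


def filter_clonal_snvs(records, clone: str, bulk: str, meta, cfg: FilterConfig,
                       exclusion=None, rescue_ids=None) -> ClonalFilterResult:
    """Clonal somatic SNVs of one clone against its matched bulk."""
    metas = _meta_by_sample(meta)
    if clone not in metas:
        raise ValueError(f"unknown clone sample {clone!r}")
    clone_meta = metas[clone]
    attrition = OrderedDict((s, 0) for s in STAGES)
    retained = []
    seen_clone = False
    for rec in records:
        call = rec.calls.get(clone)
        if call is not None:
            seen_clone = True
        # SNV-like rows only (multi-allelic SNV rows are counted, then
        # rejected at their gate); indels go through filter_indels
        if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alts):
            continue
        if cfg.allowed_contigs is not None and rec.contig not in cfg.allowed_contigs:
            continue
        if call is None or not call.is_alt:
            continue
        bulk_call = rec.calls.get(bulk)
        if bulk_call is None:
            raise ValueError(f"bulk sample {bulk!r} absent at {rec.contig}:{rec.pos}")
        attrition["candidate"] += 1
        stage = _site_gates(rec, cfg, cfg.snv_qual_min, exclusion, rescue_ids)
        if stage is not None:
            attrition[stage] += 1
            continue
        male_x = _is_male_x(rec, clone_meta, cfg)
        if not _clone_quality_ok(call, male_x, cfg):
            attrition["clone_quality"] += 1
            continue
        if not _bulk_quality_ok(bulk_call, male_x, cfg):
            attrition["bulk_quality"] += 1
            continue
        if not _clonality_ok(rec, call, male_x, clone_meta, cfg):
            attrition["clonality_vaf"] += 1
            continue
        retained.append(rec)
    if not seen_clone:
        raise ValueError(f"clone sample {clone!r} absent from records")
    return ClonalFilterResult(retained=retained, attrition=attrition)


# ---------------------------------------------------------------------------
# Clonality check (two-component beta-binomial EM)
# ---------------------------------------------------------------------------

@dataclass
class ClonalityReport:
    passed: bool
    weights: tuple          # (clonal, subclonal)
    means: tuple            # component means, same order
    rhos: tuple             # overdispersions
    converged: bool
    n_iter: int
    n_sites: int


def _bb_logpmf(k, n, mean, rho):
    rho = np.clip(rho, 1e-6, 0.999)
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    s = (1 - rho) / rho
    return stats.betabinom.logpmf(k, n, mean * s, (1 - mean) * s)


def _weighted_bb_mle(k, n, w, mean0, rho0):
    def neg(theta):
        mean = 1 / (1 + np.exp(-theta[0]))
        rho = 1 / (1 + np.exp(-theta[1]))
        return -(w * _bb_logpmf(k, n, mean, rho)).sum()

    x0 = [np.log(mean0 / (1 - mean0)), np.log(rho0 / (1 - rho0))]
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
    mean = 1 / (1 + np.exp(-res.x[0]))
    rho = 1 / (1 + np.exp(-res.x[1]))
    return float(mean), float(rho)


def clonality_check(alt, depth, cfg: FilterConfig, max_iter: int = 50,
                    tol: float = 1e-4, max_sites: int = 500,
                    seed: int = 0) -> ClonalityReport:
    """Check that a clone's candidate VAF distribution is clonal.

    Fits a two-component beta-binomial mixture to (alt, depth) pairs by EM;
    the clone passes when the weight of the component whose mean lies
    nearest 0.5 reaches ``cfg.clonality_pass_weight``.  Non-convergence is
    reported, never raised.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 1:
        raise ValueError("alt and depth must be equal-length 1-D arrays")
    if len(alt) < 20:
        raise ValueError("clonality check needs at least 20 candidate sites")
    if len(alt) > max_sites:
        idx = np.random.default_rng(seed).choice(len(alt), max_sites, replace=False)
        alt, depth = alt[idx], depth[idx]

    means = np.array([0.45, 0.12])
    rhos = np.array([0.02, 0.02])
    weights = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = np.vstack([
            np.log(weights[j]) + _bb_logpmf(alt, depth, means[j], rhos[j])
            for j in range(2)
        ])
        ll_site = np.logaddexp(log_comp[0], log_comp[1])
        ll = ll_site.sum()
        resp = np.exp(log_comp - ll_site)
        weights = resp.sum(axis=1) / len(alt)
        weights = np.clip(weights, 1e-6, 1 - 1e-6)
        weights = weights / weights.sum()
        for j in range(2):
            if resp[j].sum() > 1e-8:
                means[j], rhos[j] = _weighted_bb_mle(alt, depth, resp[j],
                                                     means[j], rhos[j])
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    clonal = int(np.argmin(np.abs(means - 0.5)))
    sub = 1 - clonal
    passed = converged and weights[clonal] >= cfg.clonality_pass_weight
    return ClonalityReport(
        passed=bool(passed),
        weights=(float(weights[clonal]), float(weights[sub])),
        means=(float(means[clonal]), float(means[sub])),
        rhos=(float(rhos[clonal]), float(rhos[sub])),
        converged=converged, n_iter=it, n_sites=len(alt),
    )


# ---------------------------------------------------------------------------
# Shared-variant calling
# ---------------------------------------------------------------------------

@dataclass
class SharedVariant:
    record: VariantRecord
    present: tuple           # qualifying 'present' clones
    absent: tuple            # qualifying 'absent' clones
    candidate_present: tuple  # all clones with a non-ref genotype
    bulk_vafs: dict          # bulk sample -> VAF (0.0 when no alt reads)


def call_shared_variants(records, clones, bulks, meta, cfg: FilterConfig,
                         exclusion=None, rescue_ids=None) -> list[SharedVariant]:
    """Variants confidently present in >=1 clone and absent in >=1 clone.

    Site-level pre-filters mirror the clonal pipeline minus the QUAL, GQ,
    DP and VAF gates (the "somatic vcf" stage); clone-grade quality is then
    required of at least one 'present' clone and bulk-grade quality
    (GQ, DP, zero alt reads) of at least one 'absent' clone.
    """
    if len(clones) < 2:
        warnings_msg = "shared-variant calling needs >= 2 clones; skipping"
        import warnings as _w

        _w.warn(warnings_msg)
        return []
    metas = _meta_by_sample(meta)
    shared = []
    for rec in records:
        if not rec.is_snv and not rec.is_indel:
            continue
        if cfg.allowed_contigs is not None and rec.contig not in cfg.allowed_contigs:
            continue
        stage = _site_gates(rec, cfg, -np.inf, exclusion, rescue_ids)
        if stage not in (None, "qual", "caller_pass"):
            continue
        if not rec.filter_pass:
            continue
        present, absent = [], []
        for c in clones:
            call = rec.calls.get(c)
            if call is None or call.gt is None:
                continue
            if call.is_alt:
                present.append(c)
            elif call.is_hom_ref:
                absent.append(c)
        if not present or not absent:
            continue
        q_present = [
            c for c in present
            if _clone_quality_ok(rec.calls[c], _is_male_x(rec, metas[c], cfg), cfg)
            and _clonality_ok(rec, rec.calls[c], _is_male_x(rec, metas[c], cfg),
                              metas[c], cfg)
        ]
        q_absent = [
            c for c in absent
            if _bulk_quality_ok(rec.calls[c], _is_male_x(rec, metas[c], cfg), cfg)
        ]
        if not q_present or not q_absent:
            continue
        bulk_vafs = {}
        for b in bulks:
            call = rec.calls.get(b)
            if call is None:
                continue
            vaf = call.vaf
            bulk_vafs[b] = 0.0 if vaf is None else float(vaf)
        shared.append(SharedVariant(
            record=rec, present=tuple(q_present), absent=tuple(q_absent),
            candidate_present=tuple(present), bulk_vafs=bulk_vafs,
        ))
    return shared


@dataclass
class SomaticCallSet:
    """Per-clone somatic sets plus the shared-variant table of one donor."""

    clonal: dict              # clone -> ClonalFilterResult (clone-vs-bulk SNVs)
    shared: list              # SharedVariant table
    indels: dict              # clone -> ClonalFilterResult (may be empty)

    def clone_sets(self, snv_only: bool = True) -> dict:
        """Each clone's somatic variant keys: clone-vs-bulk clonal calls
        united with the shared variants it qualifies as 'present' in.
        Early (bulk-subclonal) mutations fail the bulk VAF=0 gate by design
        and are recovered through the shared route."""
        out = {c: {r.key for r in res.retained if r.is_snv or not snv_only}
               for c, res in self.clonal.items()}
        for sv in self.shared:
            if snv_only and not sv.record.is_snv:
                continue
            for c in sv.present:
                if c in out:
                    out[c].add(sv.record.key)
        return out

    def clone_records(self, snv_only: bool = True) -> dict:
        """Like :meth:`clone_sets` but keeps the records."""
        out = {c: {r.key: r for r in res.retained if r.is_snv or not snv_only}
               for c, res in self.clonal.items()}
        for sv in self.shared:
            if snv_only and not sv.record.is_snv:
                continue
            for c in sv.present:
                if c in out:
                    out[c].setdefault(sv.record.key, sv.record)
        return {c: list(d.values()) for c, d in out.items()}


def call_somatic(records, clones, bulk, meta, cfg: FilterConfig,
                 exclusion=None, rescue_ids=None,
                 with_indels: bool = True) -> SomaticCallSet:
    """Run the full per-donor somatic pipeline: clone-vs-bulk clonal SNVs
    per clone, the shared-variant table, and (optionally) clonal indels."""
    clonal = {
        c: filter_clonal_snvs(records, c, bulk, meta, cfg, exclusion, rescue_ids)
        for c in clones
    }
    shared = call_shared_variants(records, clones, [bulk], meta, cfg,
                                  exclusion, rescue_ids)
    indels = {}
    if with_indels:
        germ = germline_indel_positions(records, bulk)
        indels = {
            c: filter_indels(records, c, bulk, germ, meta, cfg,
                             exclusion, rescue_ids)
            for c in clones
        }
    return SomaticCallSet(clonal=clonal, shared=shared, indels=indels)


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

def germline_indel_positions(records, bulk: str) -> list[tuple]:
    """(contig, pos) of indels genotyped non-reference in the bulk."""
    out = []
    for rec in records:
        if not rec.is_indel:
            continue
        call = rec.calls.get(bulk)
        if call is not None and call.is_alt:
            out.append((rec.contig, rec.pos))
    return out


def filter_indels(records, clone: str, bulk: str, germline_indels, meta,
                  cfg: FilterConfig, exclusion=None,
                  rescue_ids=None) -> ClonalFilterResult:
    """Clonal somatic indels: SNV rules with QUAL >= 250, GQ >= 99 on both
    samples, and removal within 100 bp of a called germline indel."""
    metas = _meta_by_sample(meta)
    clone_meta = metas[clone]
    by_contig: dict[str, list[int]] = {}
    for contig, pos in germline_indels:
        by_contig.setdefault(contig, []).append(pos)
    for v in by_contig.values():
        v.sort()
    attrition = OrderedDict((s, 0) for s in STAGES + ("germline_proximity",))
    retained = []
    flank = cfg.germline_indel_flank_bp
    for rec in records:
        if not rec.is_indel:
            continue
        if cfg.allowed_contigs is not None and rec.contig not in cfg.allowed_contigs:
            continue
        call = rec.calls.get(clone)
        if call is None or not call.is_alt:
            continue
        bulk_call = rec.calls.get(bulk)
        if bulk_call is None:
            raise ValueError(f"bulk sample {bulk!r} absent at {rec.contig}:{rec.pos}")
        attrition["candidate"] += 1
        stage = _site_gates(rec, cfg, cfg.indel_qual_min, exclusion, rescue_ids)
        if stage is not None:
            attrition[stage] += 1
            continue
        positions = by_contig.get(rec.contig, [])
        i = np.searchsorted(positions, rec.pos)
        near = (
            (i > 0 and rec.pos - positions[i - 1] <= flank)
            or (i < len(positions) and positions[i] - rec.pos <= flank)
        )
        if near:
            attrition["germline_proximity"] += 1
            continue
        male_x = _is_male_x(rec, clone_meta, cfg)
        if not _clone_quality_ok(call, male_x, cfg, gq_min=cfg.indel_gq_min):
            attrition["clone_quality"] += 1
            continue
        if not _bulk_quality_ok(bulk_call, male_x, cfg, gq_min=cfg.indel_gq_min):
            attrition["bulk_quality"] += 1
            continue
        if not _clonality_ok(rec, call, male_x, clone_meta, cfg):
            attrition["clonality_vaf"] += 1
            continue
        retained.append(rec)
    return ClonalFilterResult(retained=retained, attrition=attrition)


# ---------------------------------------------------------------------------
# Driver candidates & DBS
# ---------------------------------------------------------------------------

def flag_driver_candidates(clonal_sets: dict, cancer_gene_list, rescue_ids):
    """Report variants with MODERATE/HIGH effect hitting the rescue-ID or
    cancer-gene lists.  A report, never an exclusion."""
    genes = set(cancer_gene_list or ())
    ids = set(rescue_ids or ())
    flagged = []
    for clone, recs in clonal_sets.items():
        for rec in recs:
            if rec.effect not in ("MODERATE", "HIGH"):
                continue
            if (set(rec.ids) & ids) or (rec.gene in genes and rec.gene is not None):
                flagged.append({"clone": clone, "contig": rec.contig,
                                "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                                "effect": rec.effect, "gene": rec.gene,
                                "ids": ";".join(rec.ids)})
    return flagged


def count_dbs(clonal_sets: dict, donor_map: dict) -> dict:
    """Per-clone double-base-substitution counts.

    A DBS is two clonal SNVs at consecutive positions on one contig in one
    clone.  A DBS recurring in several clones of one donor is credited to a
    single clone (first in sample-ID order).
    """
    pair_sets: dict[str, set] = {}
    for clone, recs in clonal_sets.items():
        keys = sorted({(r.contig, r.pos, r.ref, r.alt) for r in recs if r.is_snv})
        pairs = set()
        for (c1, p1, r1, a1), (c2, p2, r2, a2) in zip(keys, keys[1:]):
            if c1 == c2 and p2 == p1 + 1:
                pairs.add((c1, p1, r1 + r2, a1 + a2))
        pair_sets[clone] = pairs
    counts = {clone: 0 for clone in clonal_sets}
    credited: set = set()
    for clone in sorted(clonal_sets):
        donor = donor_map.get(clone, clone)
        for pair in sorted(pair_sets[clone]):
            key = (donor, pair)
            if key in credited:
                continue
            credited.add(key)
            counts[clone] += 1
    return counts
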