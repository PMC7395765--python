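"""Synthetic embryo / cohort generator.

Generates a fully specified fetal cohort with the statistical structure the
downstream analysis assumes: a strictly binary pre-gastrulation cell
division tree with Poisson mutations per division, germ-layer allocation
with tunable ectoderm asymmetry, clone-specific late mutations drawn from a
signature mixture, heterozygous germline variants, in-vitro subclonal
culture artifacts, sequencing-error singletons, and binomial read sampling
at ~30x depth -- including a trisomic proxy contig with shifted expected
VAF (1/3 for one mutated copy of three) and hemizygous male X (VAF 1).

The generator is the ground truth for every recovery experiment: it labels
each variant (germline / early:<branch> / late:<clone> / invitro:<clone> /
error), records each donor's true induced lineage tree and the true bulk
contribution of every early branch, and exposes per-clone true loads.

Two light-weight companions, :func:`simulate_burden_table` and
:func:`simulate_rate_table`, draw burden observations directly from the
inferential mixed model (constant trisomy excess, donor random slope,
per-group residual SD) for the model-recovery and calibration experiments,
where the embryo-level machinery would only add noise and cost.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import CONTEXTS_96
from .signatures import SignatureCatalog
from .variant_io import SampleCall, SampleMeta, VariantRecord, write_fasta, write_metadata

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
_ERR = 1e-3          # per-read error rate of the genotype-likelihood model
_LN10 = np.log(10.0)

DEFAULT_GENOME = (
    ("chr1", 2_000_000), ("chr2", 2_000_000), ("chr3", 2_000_000),
    ("chr4", 2_000_000), ("chr21", 2_000_000), ("chrX", 2_000_000),
)


# ---------------------------------------------------------------------------
# Synthetic signature catalog
# ---------------------------------------------------------------------------

def dirichlet_signature_catalog(n_signatures: int = 10, seed: int = 0,
                                concentration: float = 0.5,
                                prefix: str = "SIG") -> SignatureCatalog:
    """Independent Dirichlet signature columns of comparable norm.

    With a moderate concentration every column spreads over many channels,
    so each mixture component contributes visibly to the reconstruction
    cosine -- the regime in which reverse selection and its bootstrap are
    informative.  (A catalog dominated by one spiky column can hide a
    40%-exposure component inside a <0.05 cosine drop; that is a known
    limitation of cosine-based selection, not of the sampler.)
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    mat = pd.DataFrame(cols, index=list(CONTEXTS_96),
                       columns=[f"{prefix}{i + 1}" for i in range(n_signatures)])
    return SignatureCatalog(mat)


def synthetic_signature_catalog(n_signatures: int = 5, seed: int = 2020,
                                names=None) -> SignatureCatalog:
    """A seeded catalog of distinguishable synthetic signatures.

    The first three columns imitate well-known processes -- a spiky
    deamination-clock signature concentrated on N[C>T]G (SBS1-like), a
    flat featureless signature (SBS5-like) and a broad T>C-rich blood
    signature (HSPC-like); further columns are sparse Dirichlet draws.
    """
    rng = np.random.default_rng(seed)
    cols = []
    ctx = list(CONTEXTS_96)
    sbs1 = np.full(96, 0.1 / 92)
    for i, c in enumerate(ctx):
        if "[C>T]G" in c:
            sbs1[i] = 0.9 / 4
    cols.append(sbs1)
    sbs5 = rng.dirichlet(np.full(96, 40.0))
    cols.append(sbs5)
    hspc = np.where([("T>C" in c) or ("T>A" in c) for c in ctx], 3.0, 0.4)
    hspc = rng.dirichlet(hspc * 2)
    cols.append(hspc)
    while len(cols) < n_signatures:
        cols.append(rng.dirichlet(np.full(96, 0.3)))
    if names is None:
        base = ["SBS1like", "SBS5like", "HSPClike"]
        names = (base + [f"SIG{i + 1}" for i in range(3, n_signatures)])[:n_signatures]
    mat = pd.DataFrame(np.column_stack(cols[:n_signatures]), index=ctx,
                       columns=list(names))
    return SignatureCatalog(mat)


# ---------------------------------------------------------------------------
# Reference genome with trinucleotide position pools
# ---------------------------------------------------------------------------

class SyntheticReference:
    """Random reference sequence plus per-context position pools.

    Pool classes index the 32 pyrimidine-strandized trinucleotides
    (pyrimidine x 5' flank x 3' flank); positions with a purine centre are
    folded in through the reverse complement.
    """

    def __init__(self, genome=DEFAULT_GENOME, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.genome = tuple((str(n), int(l)) for n, l in genome)
        self.names = [n for n, _ in self.genome]
        self.codes = {n: rng.integers(0, 4, size=l, dtype=np.int8)
                      for n, l in self.genome}
        pool_contig, pool_pos = [[] for _ in range(32)], [[] for _ in range(32)]
        for ci, (name, _) in enumerate(self.genome):
            s = self.codes[name].astype(np.int16)
            left, mid, right = s[:-2], s[1:-1], s[2:]
            is_pyr = (mid == 1) | (mid == 3)
            pyr_idx = np.where(is_pyr, (mid == 3).astype(np.int16),
                               (mid == 0).astype(np.int16))  # C->0, T->1
            five = np.where(is_pyr, left, 3 - right)
            three = np.where(is_pyr, right, 3 - left)
            cls = pyr_idx * 16 + five * 4 + three
            pos0 = np.arange(1, len(s) - 1, dtype=np.int32)
            order = np.argsort(cls, kind="stable")
            cls_sorted = cls[order]
            bounds = np.searchsorted(cls_sorted, np.arange(33))
            for k in range(32):
                sel = order[bounds[k]:bounds[k + 1]]
                pool_contig[k].append(np.full(len(sel), ci, dtype=np.int16))
                pool_pos[k].append(pos0[sel])
        self.pool_contig = [np.concatenate(a) for a in pool_contig]
        self.pool_pos = [np.concatenate(a) for a in pool_pos]

    def sequence(self, name: str) -> str:
        return _BASES[self.codes[name]].tobytes().decode()

    def sequences(self) -> dict:
        return {n: self.sequence(n) for n in self.names}

    def base(self, contig: str, pos0: int) -> str:
        return _BASE_STR[self.codes[contig][pos0]]


def _channel_class_and_alts(ch: int):
    """Pool class and (pyrimidine-strand ref, alt) of channel index ch."""
    sub = ch // 16
    pyr_idx = 0 if sub < 3 else 1
    five, three = (ch % 16) // 4, ch % 4
    ref = "CT"[pyr_idx]
    alt = {0: "A", 1: "G", 2: "T", 3: "A", 4: "C", 5: "G"}[sub]
    return pyr_idx * 16 + five * 4 + three, ref, alt


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    n_donors_d21: int = 5
    n_donors_t21: int = 4
    clones_per_donor: int = 5
    hspc_fraction: float = 0.6
    age_years: tuple | None = None        # per donor; default GA 12-17wk - 2wk
    pre_gastrulation_divisions: int = 7
    mu_early: float = 2.5                 # mutations per division
    extra_early_t21: float = 0.4          # extra per division, trisomic donors
    annual_rate: float = 100.0            # late mutations per year
    extra_rate_t21: float = 180.0         # extra per year, trisomic donors
    signature_weights: tuple | None = None
    depth_mean: float = 30.0
    n_germline: int = 2000
    germline_indel_fraction: float = 0.1
    n_invitro: int = 50                   # per clone
    invitro_vaf_range: tuple = (0.02, 0.12)
    indels_per_clone: float = 2.0         # Poisson mean, late somatic indels
    ectoderm_dominance: float = 0.5
    bulk_cells: int = 500
    genome: tuple = DEFAULT_GENOME
    trisomy_contig: str = "chr21"
    x_contig: str = "chrX"
    callable_fraction: float = 0.9
    error_rate: float = 1e-3              # singleton alt reads /site/sample
    dp_floor: int = 20                    # adequate depth inside callable mask
    balanced_clone_sampling: bool = True  # spread clones over both first lineages
    seed: int = 0
    catalog: SignatureCatalog | None = None

    def __post_init__(self):
        for name in ("n_donors_d21", "n_donors_t21", "clones_per_donor",
                     "pre_gastrulation_divisions", "n_germline", "n_invitro",
                     "bulk_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mu_early", "extra_early_t21", "annual_rate",
                     "extra_rate_t21", "error_rate", "indels_per_clone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.invitro_vaf_range
        if not (0 < lo <= hi < 0.3):
            raise ValueError("invitro_vaf_range must lie within (0, 0.3)")
        if not 0 <= self.ectoderm_dominance <= 1:
            raise ValueError("ectoderm_dominance must be in [0, 1]")
        if not 0 < self.callable_fraction <= 1:
            raise ValueError("callable_fraction must be in (0, 1]")
        if self.catalog is None:
            self.catalog = synthetic_signature_catalog()
        if self.signature_weights is None:
            w = np.zeros(len(self.catalog))
            w[: min(3, len(w))] = (0.45, 0.4, 0.15)[: min(3, len(w))]
            self.signature_weights = tuple(w / w.sum())
        w = np.asarray(self.signature_weights, dtype=float)
        if len(w) != len(self.catalog) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("signature_weights must be a simplex over catalog columns")
        if self.age_years is not None and len(self.age_years) != self.n_donors:
            raise ValueError("age_years must have one entry per donor")

    @property
    def n_donors(self) -> int:
        return self.n_donors_d21 + self.n_donors_t21

    def donor_ages(self) -> np.ndarray:
        if self.age_years is not None:
            return np.asarray(self.age_years, dtype=float)
        weeks = np.linspace(12, 17, self.n_donors) - 2.0   # GA minus 2 weeks
        return weeks * 7.0 / 365.25


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass
class DonorData:
    donor_id: str
    trisomy21: bool
    sex: str
    age: float
    clones: list
    cell_types: dict
    bulk_id: str
    variants: pd.DataFrame          # full truth table (callable + not)
    calls: dict                     # sample -> dict of arrays over callable rows
    obs_index: np.ndarray           # indices of callable rows in `variants`
    tree_newick: str
    branch_truth: pd.DataFrame
    qual: np.ndarray                # per callable row
    mq: np.ndarray

    @property
    def samples(self) -> list:
        return self.clones + [self.bulk_id]

    def to_records(self, samples=None) -> list:
        """Materialize callable rows as VariantRecord objects."""
        samples = self.samples if samples is None else list(samples)
        sub = self.variants.iloc[self.obs_index]
        contigs = sub["contig"].to_numpy()
        poss = sub["pos"].to_numpy()
        refs = sub["ref"].to_numpy()
        alts = sub["alt"].to_numpy()
        call_arrays = [(s, self.calls[s]) for s in samples]
        records = []
        for i in range(len(sub)):
            calls = {}
            for s, arr in call_arrays:
                g = arr["gt"][i]
                gt = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                calls[s] = SampleCall(gt=gt, gq=float(arr["gq"][i]),
                                      dp=int(arr["dp"][i]),
                                      ad_ref=int(arr["ad_ref"][i]),
                                      ad_alt=int(arr["ad_alt"][i]))
            records.append(VariantRecord(
                contig=contigs[i], pos=int(poss[i]), ref=refs[i],
                alts=(alts[i],), qual=float(self.qual[i]), mq=float(self.mq[i]),
                calls=calls))
        return records

    # -- truth accessors ----------------------------------------------------

    def _keys(self, mask) -> set:
        sub = self.variants[mask]
        return {(r.contig, r.pos, r.ref, r.alt) for r in sub.itertuples()}

    def true_clonal_set(self, clone: str, callable_only: bool = True,
                        snv_only: bool = True) -> set:
        v = self.variants
        carried = v["carriers"].map(lambda c: clone in c)
        mask = v["origin"].isin(["early", "late"]) & carried
        if callable_only:
            mask &= v["callable"]
        if snv_only:
            mask &= v["vtype"] == "snv"
        return self._keys(mask)

    def true_germline(self) -> set:
        return self._keys(self.variants["origin"] == "germline")

    def true_invitro(self, clone: str) -> set:
        v = self.variants
        return self._keys((v["origin"] == "invitro")
                          & v["carriers"].map(lambda c: clone in c)
                          & v["callable"])

    def true_load(self, clone: str, exclude_contigs=()) -> int:
        v = self.variants
        mask = (v["origin"].isin(["early", "late"])
                & v["carriers"].map(lambda c: clone in c)
                & (v["vtype"] == "snv"))
        if exclude_contigs:
            mask &= ~v["contig"].isin(list(exclude_contigs))
        return int(mask.sum())

    def true_early_load(self, clone: str) -> int:
        v = self.variants
        mask = (v["origin"] == "early") & v["carriers"].map(lambda c: clone in c)
        return int(mask.sum())


@dataclass
class SimulatedCohort:
    config: CohortConfig
    reference: SyntheticReference
    donors: list
    meta: list = field(default_factory=list)

    def metadata_frame(self) -> pd.DataFrame:
        cols = ["sample_id", "donor_id", "role", "cell_type", "trisomy21",
                "sex", "age_since_conception"]
        return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in self.meta])

    def donor(self, donor_id: str) -> DonorData:
        for d in self.donors:
            if d.donor_id == donor_id:
                return d
        raise KeyError(donor_id)


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _ancestors(leaf: int) -> list:
    out = []
    v = leaf
    while v > 1:
        out.append(v)
        v //= 2
    return out


def _leaf_range(v: int, depth_v: int, d: int):
    k = d - depth_v
    return v << k, (v + 1) << k


def _depth(v: int) -> int:
    return v.bit_length() - 1


class _InducedNode:
    __slots__ = ("clones", "children", "name", "length")

    def __init__(self, clones, children, name=None):
        self.clones = clones
        self.children = children
        self.name = name
        self.length = 0.0


def _induced_tree(v, d, leaf_to_clone):
    if _depth(v) == d:
        c = leaf_to_clone.get(v)
        return _InducedNode(frozenset([c]), [], name=c) if c else None
    left = _induced_tree(2 * v, d, leaf_to_clone)
    right = _induced_tree(2 * v + 1, d, leaf_to_clone)
    if left and right:
        return _InducedNode(left.clones | right.clones, [left, right])
    return left or right


def _newick(node, lengths) -> str:
    def rec(n):
        ln = lengths.get(n.clones, 0.0)
        if not n.children:
            return f"{n.name}:{ln:g}"
        inner = ",".join(rec(c) for c in n.children)
        return f"({inner}):{ln:g}"

    if node is None:
        return ";"
    return rec(node).rsplit(":", 1)[0] + ";"


def simulate_embryo(config: CohortConfig,
                    reference: SyntheticReference | None = None) -> SimulatedCohort:
    """Simulate the full cohort.  Deterministic given ``config.seed``.

    A shared :class:`SyntheticReference` may be passed in to amortize the
    position-pool construction over replicate cohorts; it must match
    ``config.genome``.
    """
    ss = np.random.SeedSequence(config.seed)
    ref_seed, *donor_seeds = ss.spawn(config.n_donors + 1)
    if reference is None:
        reference = SyntheticReference(config.genome, seed=ref_seed)
    elif reference.genome != tuple((str(n), int(l)) for n, l in config.genome):
        raise ValueError("reference genome does not match config.genome")

    ages = config.donor_ages()
    trisomy = [False] * config.n_donors_d21 + [True] * config.n_donors_t21
    donors = []
    meta = []
    for i in range(config.n_donors):
        donor_id = f"{'T' if trisomy[i] else 'D'}{i + 1:02d}"
        sex = "M" if i % 2 == 0 else "F"
        dd = _simulate_donor(config, reference, donor_id, trisomy[i], sex,
                             float(ages[i]), np.random.default_rng(donor_seeds[i]))
        donors.append(dd)
        for c in dd.clones:
            meta.append(SampleMeta(c, donor_id, "clone", dd.cell_types[c],
                                   trisomy[i], sex, float(ages[i])))
        meta.append(SampleMeta(dd.bulk_id, donor_id, "bulk", "other",
                               trisomy[i], sex, float(ages[i])))
    return SimulatedCohort(config=config, reference=reference, donors=donors,
                           meta=meta)


def _clonal_vaf(contig, trisomy21, sex, cfg) -> float:
    if trisomy21 and contig == cfg.trisomy_contig:
        return 1.0 / 3.0
    if sex == "M" and contig == cfg.x_contig:
        return 1.0
    return 0.5


def _simulate_donor(cfg: CohortConfig, ref: SyntheticReference, donor_id: str,
                    t21: bool, sex: str, age: float, rng) -> DonorData:
    d = cfg.pre_gastrulation_divisions
    n_leaves = 1 << d
    n_clones = cfg.clones_per_donor
    n_hspc = int(np.ceil(n_clones * cfg.hspc_fraction))
    clones = [f"{donor_id}-H{j + 1}" for j in range(n_hspc)] + \
             [f"{donor_id}-I{j + 1}" for j in range(n_clones - n_hspc)]
    cell_types = {c: ("HSPC" if c.split("-")[-1].startswith("H") else "ISC")
                  for c in clones}
    bulk_id = f"{donor_id}-bulk"

    # --- clone leaves (optionally balanced over the first two lineages) ---
    if cfg.balanced_clone_sampling and n_clones >= 2 and d >= 1:
        half = n_leaves // 2
        n_first = n_clones // 2 + (n_clones % 2) * int(rng.random() < 0.5)
        first = rng.choice(half, size=n_first, replace=False)
        second = rng.choice(half, size=n_clones - n_first, replace=False) + half
        leaves = np.concatenate([first, second]) + n_leaves
    else:
        leaves = rng.choice(n_leaves, size=n_clones, replace=False) + n_leaves
    rng.shuffle(leaves)
    leaf_to_clone = {int(l): c for l, c in zip(leaves, clones)}
    anc = {c: set(_ancestors(int(l))) for l, c in zip(leaves, clones)}

    # --- bulk skin: ectoderm cells with first-daughter dominance ----------
    side_first = rng.random(cfg.bulk_cells) < cfg.ectoderm_dominance
    half = n_leaves // 2
    bulk_leaves = np.where(
        side_first,
        rng.integers(0, half, size=cfg.bulk_cells),
        rng.integers(half, n_leaves, size=cfg.bulk_cells),
    ) + n_leaves
    bulk_sorted = np.sort(bulk_leaves)

    # --- early mutations on division edges --------------------------------
    mu = cfg.mu_early + (cfg.extra_early_t21 if t21 else 0.0)
    edges = np.arange(2, 2 * n_leaves)
    edge_counts = rng.poisson(mu, size=len(edges))
    early_rows = []          # (edge, carriers tuple, bulk_frac)
    branch_len: dict = {}
    branch_top: dict = {}
    for v, m in zip(edges, edge_counts):
        if m == 0:
            continue
        carriers = tuple(sorted(c for c in clones if v in anc[c]))
        lo, hi = _leaf_range(int(v), _depth(int(v)), d)
        cnt = np.searchsorted(bulk_sorted, hi) - np.searchsorted(bulk_sorted, lo)
        frac = cnt / cfg.bulk_cells
        if not carriers:
            continue   # unobservable in any sequenced clone
        key = frozenset(carriers)
        branch_len[key] = branch_len.get(key, 0) + int(m)
        if key not in branch_top or _depth(int(v)) < branch_top[key][0]:
            branch_top[key] = (_depth(int(v)), frac)
        early_rows.extend([(int(v), carriers, frac)] * int(m))

    induced = _induced_tree(1, d, leaf_to_clone)
    tree_newick = _newick(induced, {k: float(v) for k, v in branch_len.items()})

    btr = []
    for key, length in sorted(branch_len.items(), key=lambda kv: sorted(kv[0])):
        btr.append({
            "branch_clones": ",".join(sorted(key)),
            "n_early_mutations": length,
            "true_cell_fraction": branch_top[key][1],
        })
    branch_truth = pd.DataFrame(btr)

    # --- category bookkeeping ---------------------------------------------
    rate = cfg.annual_rate + (cfg.extra_rate_t21 if t21 else 0.0)
    n_late = rng.poisson(rate * age, size=n_clones)
    n_indel = rng.poisson(cfg.indels_per_clone, size=n_clones)
    lo_v, hi_v = cfg.invitro_vaf_range

    origins, carriers_col, bulk_frac_col = [], [], []
    for _, carriers, frac in early_rows:
        origins.append("early")
        carriers_col.append(carriers)
        bulk_frac_col.append(frac)
    for j, c in enumerate(clones):
        origins.extend(["late"] * int(n_late[j]))
        carriers_col.extend([(c,)] * int(n_late[j]))
        bulk_frac_col.extend([0.0] * int(n_late[j]))
    invitro_vaf = []
    for j, c in enumerate(clones):
        origins.extend(["invitro"] * cfg.n_invitro)
        carriers_col.extend([(c,)] * cfg.n_invitro)
        bulk_frac_col.extend([0.0] * cfg.n_invitro)
        invitro_vaf.append(rng.uniform(lo_v, hi_v, size=cfg.n_invitro))
    n_somatic_snv = len(origins)

    # channels and positions for somatic SNVs
    weights = np.asarray(cfg.signature_weights)
    p_channel = cfg.catalog.matrix.to_numpy() @ weights
    p_channel = p_channel / p_channel.sum()
    channels = rng.choice(96, size=n_somatic_snv, p=p_channel)
    contig_idx = np.empty(n_somatic_snv, dtype=np.int32)
    pos0 = np.empty(n_somatic_snv, dtype=np.int64)
    refs = np.empty(n_somatic_snv, dtype=object)
    alts = np.empty(n_somatic_snv, dtype=object)
    by_class: dict[int, list] = {}
    for i, ch in enumerate(channels):
        cls, pyr_ref, pyr_alt = _channel_class_and_alts(int(ch))
        by_class.setdefault(cls, []).append((i, pyr_ref, pyr_alt))
    for cls, items in by_class.items():
        pool_c, pool_p = ref.pool_contig[cls], ref.pool_pos[cls]
        k = len(items)
        if len(pool_c) < k:
            raise ValueError(
                f"genome too small: context pool {cls} has {len(pool_c)} "
                f"positions for {k} requested mutations")
        sel = rng.choice(len(pool_c), size=k, replace=False)
        for (i, pyr_ref, pyr_alt), s in zip(items, sel):
            ci, p0 = int(pool_c[s]), int(pool_p[s])
            contig_idx[i] = ci
            pos0[i] = p0
            actual = _BASE_STR[ref.codes[ref.names[ci]][p0]]
            if actual == pyr_ref:
                refs[i], alts[i] = pyr_ref, pyr_alt
            else:
                refs[i], alts[i] = actual, _COMP[pyr_alt]

    # germline SNVs / indels and somatic indels at uniform positions
    lengths = np.array([l for _, l in ref.genome], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    genome_size = int(cum[-1])

    def uniform_positions(n, margin=3):
        offs = rng.integers(0, genome_size, size=n)
        ci = np.searchsorted(cum, offs, side="right") - 1
        p0 = offs - cum[ci]
        p0 = np.clip(p0, 1, lengths[ci] - 1 - margin)
        return ci.astype(np.int32), p0.astype(np.int64)

    n_germ_indel = int(cfg.n_germline * cfg.germline_indel_fraction)
    n_germ_snv = cfg.n_germline - n_germ_indel
    g_ci, g_p0 = uniform_positions(cfg.n_germline)
    gi_ci, gi_p0 = g_ci[n_germ_snv:], g_p0[n_germ_snv:]
    g_ci, g_p0 = g_ci[:n_germ_snv], g_p0[:n_germ_snv]
    si_total = int(n_indel.sum())
    si_ci, si_p0 = uniform_positions(si_total)

    # sequencing-error singleton candidates inside the callable mask
    mask_len = (lengths * cfg.callable_fraction).astype(np.int64)
    mask_start = np.array([rng.integers(0, l - m + 1)
                           for l, m in zip(lengths, mask_len)], dtype=np.int64)
    mask_total = int(mask_len.sum())
    mask_cum = np.concatenate([[0], np.cumsum(mask_len)])
    samples = clones + [bulk_id]
    n_err = rng.poisson(cfg.error_rate * mask_total, size=len(samples))
    e_ci_all, e_p0_all, e_sample = [], [], []
    for si, n in enumerate(n_err):
        offs = rng.integers(0, mask_total, size=n)
        ci = np.searchsorted(mask_cum, offs, side="right") - 1
        p0 = offs - mask_cum[ci] + mask_start[ci]
        p0 = np.clip(p0, 1, lengths[ci] - 2)
        e_ci_all.append(ci.astype(np.int32))
        e_p0_all.append(p0.astype(np.int64))
        e_sample.extend([si] * n)
    e_ci = np.concatenate(e_ci_all) if e_ci_all else np.empty(0, np.int32)
    e_p0 = np.concatenate(e_p0_all) if e_p0_all else np.empty(0, np.int64)
    e_sample = np.asarray(e_sample, dtype=np.int32)

    # --- assemble the truth table -----------------------------------------
    def seq_base(ci, p0):
        return _BASE_STR[ref.codes[ref.names[int(ci)]][int(p0)]]

    rows = {
        "contig": [], "pos": [], "ref": [], "alt": [], "vtype": [],
        "origin": [], "carriers": [], "bulk_frac": [], "channel": [],
        "err_sample": [], "invitro_vaf": [],
    }

    def add(contig, pos0_, ref_, alt_, vtype, origin, carriers, bulk_frac,
            channel="", err_sample=-1, iv=np.nan):
        rows["contig"].append(contig)
        rows["pos"].append(int(pos0_) + 1)
        rows["ref"].append(ref_)
        rows["alt"].append(alt_)
        rows["vtype"].append(vtype)
        rows["origin"].append(origin)
        rows["carriers"].append(carriers)
        rows["bulk_frac"].append(bulk_frac)
        rows["channel"].append(channel)
        rows["err_sample"].append(err_sample)
        rows["invitro_vaf"].append(iv)

    iv_flat = np.concatenate(invitro_vaf) if invitro_vaf else np.empty(0)
    iv_iter = iter(iv_flat)
    for i in range(n_somatic_snv):
        name = ref.names[contig_idx[i]]
        iv = next(iv_iter) if origins[i] == "invitro" else np.nan
        add(name, pos0[i], refs[i], alts[i], "snv", origins[i],
            carriers_col[i], bulk_frac_col[i],
            channel=CONTEXTS_96[channels[i]], iv=iv)
    for ci, p0 in zip(g_ci, g_p0):
        name = ref.names[ci]
        b = seq_base(ci, p0)
        alt = _BASE_STR[(_BASE_STR.index(b) + int(rng.integers(1, 4))) % 4]
        add(name, p0, b, alt, "snv", "germline", tuple(clones), 0.0)
    for ci, p0 in zip(gi_ci, gi_p0):
        name = ref.names[ci]
        anchor = seq_base(ci, p0)
        if rng.random() < 0.5:
            ins = "".join(_BASE_STR[j] for j in rng.integers(0, 4, size=2))
            add(name, p0, anchor, anchor + ins, "indel", "germline",
                tuple(clones), 0.0)
        else:
            deleted = anchor + seq_base(ci, p0 + 1) + seq_base(ci, p0 + 2)
            add(name, p0, deleted, anchor, "indel", "germline",
                tuple(clones), 0.0)
    k = 0
    for j, c in enumerate(clones):
        for _ in range(int(n_indel[j])):
            ci, p0 = si_ci[k], si_p0[k]
            k += 1
            name = ref.names[ci]
            anchor = seq_base(ci, p0)
            if rng.random() < 0.5:
                ins = "".join(_BASE_STR[x] for x in rng.integers(0, 4, size=1))
                add(name, p0, anchor, anchor + ins, "indel", "late", (c,), 0.0)
            else:
                add(name, p0, anchor + seq_base(ci, p0 + 1), anchor, "indel",
                    "late", (c,), 0.0)
    for ci, p0, si in zip(e_ci, e_p0, e_sample):
        name = ref.names[ci]
        b = seq_base(ci, p0)
        alt = _BASE_STR[(_BASE_STR.index(b) + int(rng.integers(1, 4))) % 4]
        add(name, p0, b, alt, "snv", "error", (), 0.0, err_sample=int(si))

    variants = pd.DataFrame(rows)
    # resolve position collisions: earlier categories take precedence
    gkey = variants["contig"].map({n: i for i, n in enumerate(ref.names)}) \
        .to_numpy() * (genome_size + 1) + variants["pos"].to_numpy()
    dup = pd.Series(gkey).duplicated(keep="first").to_numpy()
    variants = variants[~dup].reset_index(drop=True)

    # callable mask membership
    cidx = variants["contig"].map({n: i for i, n in enumerate(ref.names)}).to_numpy()
    p0 = variants["pos"].to_numpy() - 1
    in_mask = (p0 >= mask_start[cidx]) & (p0 < mask_start[cidx] + mask_len[cidx])
    variants["callable"] = in_mask

    # true VAF per sample
    n_var = len(variants)
    V = np.zeros((n_var, len(samples)))
    phi = np.array([_clonal_vaf(c, t21, sex, cfg) for c in variants["contig"]])
    origin = variants["origin"].to_numpy()
    carr = variants["carriers"].to_numpy()
    bulk_frac = variants["bulk_frac"].to_numpy(dtype=float)
    ivvaf = variants["invitro_vaf"].to_numpy(dtype=float)
    for si, s in enumerate(clones):
        carried = np.fromiter((s in cs for cs in carr), bool, count=n_var)
        V[:, si] = np.where(carried & (origin != "invitro"), phi, 0.0)
        iv_mask = carried & (origin == "invitro")
        V[iv_mask, si] = ivvaf[iv_mask]
    bcol = len(samples) - 1
    V[:, bcol] = np.where(origin == "germline", phi, 0.0)
    early_mask = origin == "early"
    V[early_mask, bcol] = bulk_frac[early_mask] * phi[early_mask]
    # germline on trisomic chr21: one of three copies or two of three
    if t21:
        g21 = (origin == "germline") & (variants["contig"] == cfg.trisomy_contig).to_numpy()
        two_copy = rng.random(n_var) < 0.5
        V[g21 & two_copy, :] = 2.0 / 3.0
    variants["true_bulk_vaf"] = V[:, bcol]

    # --- reads, genotypes, qualities over callable rows --------------------
    obs_index = np.where(variants["callable"].to_numpy())[0]
    n_obs = len(obs_index)
    Vo = V[obs_index]
    dp = rng.poisson(cfg.depth_mean, size=(n_obs, len(samples)))
    bad = dp < cfg.dp_floor
    while bad.any():
        dp[bad] = rng.poisson(cfg.depth_mean, size=int(bad.sum()))
        bad = dp < cfg.dp_floor
    alt = rng.binomial(dp, Vo)
    inject = rng.random((n_obs, len(samples))) < cfg.error_rate
    alt = np.minimum(dp, alt + inject)
    err_sample = variants["err_sample"].to_numpy()[obs_index]
    err_rows = np.where(err_sample >= 0)[0]
    alt[err_rows, err_sample[err_rows]] = 1

    from scipy.stats import binom as _binom

    ll = np.stack([_binom.logpmf(alt, dp, p) for p in (_ERR, 0.5, 1 - _ERR)])
    gt = np.argmax(ll, axis=0).astype(np.int8)
    ll_sorted = np.sort(ll, axis=0)
    gq = np.clip(10.0 * (ll_sorted[2] - ll_sorted[1]) / _LN10, 0, 99)
    gq = np.round(gq).astype(np.int16)
    ll_ref = ll[0]
    ll_best = ll_sorted[2]
    contrib = np.where(gt > 0, np.maximum(0.0, 10.0 * (ll_best - ll_ref) / _LN10), 0.0)
    qual = np.minimum(2500.0, contrib.sum(axis=1))
    gt[err_rows, err_sample[err_rows]] = 1
    gq[err_rows, err_sample[err_rows]] = 0
    qual[err_rows] = rng.uniform(5, 45, size=len(err_rows))
    mq = np.full(n_obs, 60.0)

    calls = {}
    for si, s in enumerate(samples):
        calls[s] = {
            "gt": gt[:, si].copy(), "gq": gq[:, si].astype(float),
            "dp": dp[:, si].astype(np.int32),
            "ad_ref": (dp[:, si] - alt[:, si]).astype(np.int32),
            "ad_alt": alt[:, si].astype(np.int32),
        }

    # sort rows genomically (records and VCFs downstream expect order)
    order = np.lexsort((variants["pos"].to_numpy(), cidx))
    variants = variants.iloc[order].reset_index(drop=True)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    obs_order = np.argsort(inv[obs_index], kind="stable")
    obs_index = np.sort(inv[obs_index])
    qual = qual[obs_order]
    mq = mq[obs_order]
    for s in samples:
        for kname in calls[s]:
            calls[s][kname] = calls[s][kname][obs_order]

    return DonorData(
        donor_id=donor_id, trisomy21=t21, sex=sex, age=age, clones=clones,
        cell_types=cell_types, bulk_id=bulk_id, variants=variants,
        calls=calls, obs_index=obs_index, tree_newick=tree_newick,
        branch_truth=branch_truth, qual=qual, mq=mq,
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _vcf_lines(donor: DonorData, sample_ids, row_mask=None):
    sub = donor.variants.iloc[donor.obs_index].reset_index(drop=True)
    n = len(sub)
    idx = np.arange(n) if row_mask is None else np.where(row_mask)[0]
    contig = sub["contig"].to_numpy()
    pos = sub["pos"].to_numpy()
    refa = sub["ref"].to_numpy()
    alta = sub["alt"].to_numpy()
    arrays = {s: donor.calls[s] for s in sample_ids}
    lines = []
    gt_txt = ("0/0", "0/1", "1/1")
    for i in idx:
        cols = [contig[i], str(pos[i]), ".", refa[i], alta[i],
                f"{donor.qual[i]:.1f}", "PASS", f"MQ={donor.mq[i]:g}",
                "GT:GQ:DP:AD"]
        for s in sample_ids:
            a = arrays[s]
            cols.append(
                f"{gt_txt[a['gt'][i]]}:{int(a['gq'][i])}:{a['dp'][i]}:"
                f"{a['ad_ref'][i]},{a['ad_alt'][i]}")
        lines.append("\t".join(cols))
    return lines


def write_cohort(cohort: SimulatedCohort, directory) -> dict:
    """Write clone and bulk VCFs, reference FASTA (+.fai), metadata and
    truth TSVs.  Returns a manifest of written paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    cfg = cohort.config
    manifest = {"vcfs": [], "trees": []}

    fasta_path = os.path.join(directory, "reference.fa")
    write_fasta(cohort.reference.sequences(), fasta_path)
    manifest["fasta"] = fasta_path

    header = ["##fileformat=VCFv4.2"]
    for name, length in cfg.genome:
        header.append(f"##contig=<ID={name},length={length}>")
    header += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]

    truth_frames = []
    load_rows = []
    contrib_frames = []
    for donor in cohort.donors:
        for clone in donor.clones:
            path = os.path.join(directory, f"{clone}.vcf")
            cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" \
                   f"{clone}\t{donor.bulk_id}"
            lines = _vcf_lines(donor, [clone, donor.bulk_id])
            with open(path, "w") as fh:
                fh.write("\n".join(header + [cols] + lines) + "\n")
            manifest["vcfs"].append(path)
        bpath = os.path.join(directory, f"{donor.bulk_id}.vcf")
        bulk_gt = donor.calls[donor.bulk_id]["gt"]
        lines = _vcf_lines(donor, [donor.bulk_id], row_mask=bulk_gt > 0)
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" \
               f"{donor.bulk_id}"
        with open(bpath, "w") as fh:
            fh.write("\n".join(header + [cols] + lines) + "\n")
        manifest["vcfs"].append(bpath)

        tv = donor.variants.copy()
        tv.insert(0, "donor_id", donor.donor_id)
        tv["carriers"] = tv["carriers"].map(lambda t: ",".join(t))
        truth_frames.append(tv.drop(columns=["err_sample"]))
        for clone in donor.clones:
            load_rows.append({
                "clone_id": clone, "donor_id": donor.donor_id,
                "true_load": donor.true_load(clone),
                "true_early_load": donor.true_early_load(clone),
            })
        tpath = os.path.join(directory, f"{donor.donor_id}.tree.nwk")
        with open(tpath, "w") as fh:
            fh.write(donor.tree_newick + "\n")
        manifest["trees"].append(tpath)
        bt = donor.branch_truth.copy()
        bt.insert(0, "donor_id", donor.donor_id)
        contrib_frames.append(bt)

    meta_path = os.path.join(directory, "metadata.tsv")
    write_metadata(cohort.meta, meta_path)
    manifest["metadata"] = meta_path
    truth_path = os.path.join(directory, "truth_variants.tsv")
    pd.concat(truth_frames).to_csv(truth_path, sep="\t", index=False)
    manifest["truth_variants"] = truth_path
    loads_path = os.path.join(directory, "truth_loads.tsv")
    pd.DataFrame(load_rows).to_csv(loads_path, sep="\t", index=False)
    manifest["truth_loads"] = loads_path
    contrib_path = os.path.join(directory, "truth_branches.tsv")
    pd.concat(contrib_frames).to_csv(contrib_path, sep="\t", index=False)
    manifest["truth_branches"] = contrib_path
    return manifest


def true_summary(cohort: SimulatedCohort) -> dict:
    """Truth tables: per-clone loads, Newick trees, branch contributions."""
    load_rows = []
    trees = {}
    contribs = []
    for donor in cohort.donors:
        trees[donor.donor_id] = donor.tree_newick
        for clone in donor.clones:
            load_rows.append({
                "clone_id": clone, "donor_id": donor.donor_id,
                "true_load": donor.true_load(clone),
                "true_early_load": donor.true_early_load(clone),
            })
        bt = donor.branch_truth.copy()
        bt.insert(0, "donor_id", donor.donor_id)
        contribs.append(bt)
    return {
        "loads": pd.DataFrame(load_rows),
        "trees": trees,
        "branch_contributions": pd.concat(contribs, ignore_index=True)
        if contribs else pd.DataFrame(),
    }


def truth_matrix(donor: DonorData, include_late: bool = True):
    """Binary clone x mutation matrix straight from the truth labels
    (bypasses filtering) -- the input for tree-recovery experiments."""
    from .lineage import ROOT_LABEL, BinaryMutationMatrix

    v = donor.variants
    mask = (v["vtype"] == "snv") & v["origin"].isin(
        ["early", "late"] if include_late else ["early"])
    sub = v[mask]
    names, rows = [], []
    mat = {}
    for r in sub.itertuples():
        name = f"{r.contig}:{r.pos}:{r.ref}>{r.alt}"
        names.append(name)
        mat[name] = {c: 1 for c in r.carriers}
        rows.append({"mutation": name, "contig": r.contig, "pos": r.pos,
                     "ref": r.ref, "alt": r.alt})
    frame = pd.DataFrame(0, index=donor.clones + [ROOT_LABEL],
                         columns=names, dtype=int)
    for name, carriers in mat.items():
        frame.loc[list(carriers), name] = 1
    meta = pd.DataFrame(rows).set_index("mutation") if rows else pd.DataFrame()
    return BinaryMutationMatrix(matrix=frame, metadata=meta)


def bulk_allele_counts(donor: DonorData) -> dict:
    """Bulk (ad_ref, ad_alt) per observable mutation name."""
    sub = donor.variants.iloc[donor.obs_index].reset_index(drop=True)
    arr = donor.calls[donor.bulk_id]
    out = {}
    for i, r in enumerate(sub.itertuples()):
        out[f"{r.contig}:{r.pos}:{r.ref}>{r.alt}"] = (
            int(arr["ad_ref"][i]), int(arr["ad_alt"][i]))
    return out


# ---------------------------------------------------------------------------
# Model-level generators for recovery / calibration experiments
# ---------------------------------------------------------------------------

def simulate_burden_table(seed=None, n_donors_d21: int = 5, n_donors_t21: int = 4,
                          clones_per_donor: int = 5, hspc_fraction: float = 0.6,
                          ages=None, baseline: float = 17.5,
                          annual_rate: float = 100.0, trisomy_excess: float = 34.0,
                          cell_type_effect: float = 0.0,
                          donor_slope_sd: float = 15.0,
                          resid_sd_d21: float = 6.5, resid_sd_t21: float = 6.5,
                          ) -> pd.DataFrame:
    """Per-clone extrapolated loads drawn from the trisomy burden model.

    load = baseline + rate x age + excess x T21 + cell effect x ISC
           + donor slope x age + N(0, group SD).
    """
    rng = np.random.default_rng(seed)
    n_donors = n_donors_d21 + n_donors_t21
    if ages is None:
        ages = (np.linspace(12, 17, n_donors) - 2.0) * 7.0 / 365.25
    ages = np.asarray(ages, dtype=float)
    rows = []
    for i in range(n_donors):
        t21 = i >= n_donors_d21
        donor = f"{'T' if t21 else 'D'}{i + 1:02d}"
        b = rng.normal(0, donor_slope_sd)
        n_h = int(np.ceil(clones_per_donor * hspc_fraction))
        for j in range(clones_per_donor):
            isc = j >= n_h
            sd = resid_sd_t21 if t21 else resid_sd_d21
            load = (baseline + annual_rate * ages[i]
                    + trisomy_excess * t21 + cell_type_effect * isc
                    + b * ages[i] + rng.normal(0, sd))
            rows.append({
                "clone_id": f"{donor}-{'I' if isc else 'H'}{j + 1}",
                "donor_id": donor, "trisomy21": bool(t21),
                "cell_type": "ISC" if isc else "HSPC",
                "age": float(ages[i]),
                "extrapolated_load": float(load),
            })
    df = pd.DataFrame(rows)
    df["rate"] = df["extrapolated_load"] / df["age"]
    return df


def simulate_early_table(seed=None, n_donors_d21: int = 5, n_donors_t21: int = 4,
                         clones_per_donor: int = 5, hspc_fraction: float = 0.6,
                         baseline: float = 17.5, trisomy_excess: float = 6.0,
                         donor_sd: float = 2.0, resid_sd: float = 4.0
                         ) -> pd.DataFrame:
    """Per-clone pre-gastrulation loads with a constant trisomy excess."""
    rng = np.random.default_rng(seed)
    n_donors = n_donors_d21 + n_donors_t21
    rows = []
    for i in range(n_donors):
        t21 = i >= n_donors_d21
        donor = f"{'T' if t21 else 'D'}{i + 1:02d}"
        b = rng.normal(0, donor_sd)
        n_h = int(np.ceil(clones_per_donor * hspc_fraction))
        for j in range(clones_per_donor):
            isc = j >= n_h
            rows.append({
                "clone_id": f"{donor}-{'I' if isc else 'H'}{j + 1}",
                "donor_id": donor, "trisomy21": bool(t21),
                "cell_type": "ISC" if isc else "HSPC",
                "early_load": float(baseline + trisomy_excess * t21 + b
                                    + rng.normal(0, resid_sd)),
            })
    return pd.DataFrame(rows)


def simulate_rate_table(seed=None, groups=None) -> pd.DataFrame:
    """Per-clone annual mutation rates across fetal / cord / post-infant
    cohorts with donor random intercepts.

    ``groups`` maps cohort -> dict(n_donors, clones_per_donor, rate,
    age_range, donor_sd, resid_sd); the defaults mirror a fetal-vs-
    post-infant haematopoietic design (fetal ~100/yr, post-infant ~17/yr).
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = {
            "fetal": dict(n_donors=3, clones_per_donor=5, rate=100.0,
                          age_range=(0.19, 0.29), donor_sd=8.0, resid_sd=18.0),
            "cord": dict(n_donors=2, clones_per_donor=2, rate=70.0,
                         age_range=(0.75, 0.78), donor_sd=6.0, resid_sd=10.0),
            "post-infant": dict(n_donors=6, clones_per_donor=3, rate=17.2,
                                age_range=(5.0, 60.0), donor_sd=3.0, resid_sd=4.0),
        }
    rows = []
    for cohort, g in groups.items():
        for i in range(g["n_donors"]):
            donor = f"{cohort[:2]}{i + 1:02d}"
            age = float(rng.uniform(*g["age_range"]))
            b = rng.normal(0, g["donor_sd"])
            for j in range(g["clones_per_donor"]):
                rate = g["rate"] + b + rng.normal(0, g["resid_sd"])
                rows.append({
                    "clone_id": f"{donor}-c{j + 1}", "donor_id": donor,
                    "cohort": cohort, "age": age, "rate": float(rate),
                    "extrapolated_load": float(rate * age),
                })
    return pd.DataFrame(rows)
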