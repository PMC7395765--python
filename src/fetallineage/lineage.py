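"""Developmental lineage trees from shared somatic mutations.

Clones of one donor are placed in a binary presence/absence matrix over
their somatic mutations (clonal plus shared calls); a zero-profile
pseudo-sample roots the tree.  Pairwise Hamming distances feed
neighbor-joining (UPGMA available behind a flag), the tree is re-rooted at
the zero profile, and every mutation is assigned to the branch above the
clade that equals its carrier set -- branch length is then its mutation
count, and carrier sets matching no clade are reported as conflicts.

Each early branch's contribution to a bulk tissue is estimated as twice
the median bulk VAF of its contributing (non-zero VAF) mutations; a
chi-square test on the per-mutation allele counts decides whether the
branch's mutations arose in different cell divisions, and pairwise Fisher
tests on summed allele counts compare branch contributions.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

ROOT_LABEL = "root"


# ---------------------------------------------------------------------------
# Binary mutation matrix
# ---------------------------------------------------------------------------

@dataclass
class BinaryMutationMatrix:
    matrix: pd.DataFrame                 # clones (+ root row) x mutations, 0/1
    metadata: pd.DataFrame               # per-mutation contig/pos/ref/alt + bulk VAFs
    dropped: list = field(default_factory=list)   # all-zero columns removed

    @property
    def clones(self) -> list:
        return [c for c in self.matrix.index if c != ROOT_LABEL]


def _mutation_key(key) -> str:
    contig, pos, ref, alt = key
    return f"{contig}:{pos}:{ref}>{alt}"


def build_matrix(shared_table, clonal_sets: dict,
                 bulk_vafs: dict | None = None) -> BinaryMutationMatrix:
    """Binary clone x mutation matrix from clonal sets and the shared table.

    Presence means membership in the clone's qualifying set (its clonal
    calls, or the qualifying 'present' side of a shared variant).  A row of
    zeros labelled ``root`` is appended; all-zero mutation columns are
    unplaceable and dropped with a log entry.
    """
    clones = sorted(clonal_sets)
    if len(clones) < 2:
        raise ValueError("need at least two clones to build a lineage matrix")
    presence: dict[tuple, set] = {}
    meta: dict[tuple, dict] = {}
    for clone, recs in clonal_sets.items():
        for rec in recs:
            key = rec.key if hasattr(rec, "key") else tuple(rec)
            presence.setdefault(key, set()).add(clone)
            meta.setdefault(key, {})
    for sv in shared_table or ():
        key = sv.record.key
        presence.setdefault(key, set()).update(sv.present)
        meta.setdefault(key, {})["bulk_vafs"] = dict(sv.bulk_vafs)

    keys = sorted(presence)
    dropped = [k for k in keys if not presence[k]]
    keys = [k for k in keys if presence[k]]
    names = [_mutation_key(k) for k in keys]
    mat = pd.DataFrame(0, index=clones + [ROOT_LABEL], columns=names, dtype=int)
    for k, name in zip(keys, names):
        mat.loc[sorted(presence[k]), name] = 1
    rows = []
    for k, name in zip(keys, names):
        contig, pos, ref, alt = k
        row = {"mutation": name, "contig": contig, "pos": pos,
               "ref": ref, "alt": alt}
        for b, v in (meta[k].get("bulk_vafs") or {}).items():
            row[f"vaf[{b}]"] = v
        rows.append(row)
    md = pd.DataFrame(rows).set_index("mutation") if rows else pd.DataFrame()
    return BinaryMutationMatrix(matrix=mat, metadata=md, dropped=dropped)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

@dataclass
class LineageTree:
    tree: TreeNode                        # rooted, zero-profile leaf removed
    matrix: BinaryMutationMatrix
    branch_mutations: dict = field(default_factory=dict)   # branch name -> [mutation]
    conflicts: list = field(default_factory=list)
    contributions: pd.DataFrame | None = None

    def branch_lengths(self) -> dict:
        return {name: len(muts) for name, muts in self.branch_mutations.items()}


def _name_internals(tree: TreeNode) -> None:
    i = 0
    for node in tree.preorder():
        if node.name is None:
            node.name = f"n{i}"
            i += 1


def build_tree(matrix: BinaryMutationMatrix, method: str = "nj") -> LineageTree:
    """Neighbor-joining tree from Hamming distances, rooted at the zero
    profile.  Negative NJ branch lengths are clamped to zero; identical
    rows yield zero-length sibling branches."""
    mat = matrix.matrix
    ids = list(mat.index)
    if len(ids) < 3:
        raise ValueError("need at least two clones plus the root row")
    X = mat.to_numpy()
    d = (X[:, None, :] != X[None, :, :]).sum(axis=2).astype(float)
    dm = DistanceMatrix(d, ids)
    if method == "nj":
        tree = nj(dm)
    elif method == "upgma":
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        tree = TreeNode.from_linkage_matrix(link, ids)
    else:
        raise ValueError(f"unknown method {method!r}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    zero_leaf = tree.find(ROOT_LABEL)
    if zero_leaf.parent is not tree:
        tree = tree.root_at(zero_leaf.parent)
        zero_leaf = tree.find(ROOT_LABEL)
    tree.remove(zero_leaf)
    # keep a trunk branch above the first split so that mutations carried
    # by every clone remain placeable
    wrapper = TreeNode()
    wrapper.append(tree)
    tree.length = 0.0
    tree = wrapper
    _name_internals(tree)
    lt = LineageTree(tree=tree, matrix=matrix)
    assign_branch_mutations(lt)
    return lt


def assign_branch_mutations(lt: LineageTree) -> None:
    """Map every mutation to the branch above the clade equal to its
    carrier set; non-clade carrier sets are conflicts."""
    mat = lt.matrix.matrix.drop(index=ROOT_LABEL)
    clades = {}
    for node in lt.tree.traverse(include_self=False):
        leaves = frozenset(l.name for l in node.tips()) or frozenset([node.name])
        clades.setdefault(leaves, node.name)
    branch_mutations = {name: [] for name in
                        (n.name for n in lt.tree.traverse(include_self=False))}
    conflicts = []
    for mut in mat.columns:
        carriers = frozenset(mat.index[mat[mut] == 1])
        node_name = clades.get(carriers)
        if node_name is None:
            conflicts.append(mut)
        else:
            branch_mutations[node_name].append(mut)
    for node in lt.tree.traverse(include_self=False):
        node.length = float(len(branch_mutations[node.name]))
    lt.branch_mutations = branch_mutations
    lt.conflicts = conflicts


def first_branches(lt: LineageTree) -> list:
    """Names of the first two (or more) developmental branches: the
    children of the first split below the trunk."""
    node = lt.tree
    while len(node.children) == 1:
        node = node.children[0]
    return [c.name for c in node.children]


# ---------------------------------------------------------------------------
# Early mutations & contributions
# ---------------------------------------------------------------------------

def early_mutations(shared_table, bulk: str):
    """Shared variants sub-clonally present in the germ-layer-discordant
    bulk (VAF > 0) -- acquired before gastrulation.

    Returns ``(early_keys, per_clone_counts)`` where a clone's early load
    counts the early variants it carries (candidate-present side).
    """
    if not shared_table:
        return set(), {}
    if all(bulk not in sv.bulk_vafs for sv in shared_table):
        raise ValueError(f"no bulk sample {bulk!r} in shared table")
    early = set()
    per_clone: dict[str, int] = {}
    for sv in shared_table:
        vaf = sv.bulk_vafs.get(bulk)
        if vaf is not None and vaf > 0:
            early.add(sv.record.key)
            for c in sv.candidate_present:
                per_clone[c] = per_clone.get(c, 0) + 1
    return early, per_clone


def branch_contribution(lt: LineageTree, bulk_counts: dict,
                        trisomy_contig: str = "chr21",
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-branch contribution to the bulk tissue.

    ``bulk_counts`` maps mutation name -> (ad_ref, ad_alt) in the bulk.
    Mutations on the trisomy-proxy contig are excluded (copy-number
    distorts their VAF).  A branch whose contributing mutations have
    significantly different allele counts (chi-square p < alpha) is split
    into per-mutation segments; otherwise the contribution is
    min(1, 2 x median non-zero VAF).  Zero-VAF mutations count as
    non-contributing; a branch with none contributing has an undefined
    contribution.
    """
    rows = []
    meta = lt.matrix.metadata
    for branch, muts in lt.branch_mutations.items():
        usable = [m for m in muts
                  if m in bulk_counts
                  and (meta.empty or meta.loc[m, "contig"] != trisomy_contig)]
        vafs, alts, refs, contributing = [], [], [], []
        for m in usable:
            ref_n, alt_n = bulk_counts[m]
            denom = ref_n + alt_n
            v = alt_n / denom if denom else 0.0
            if alt_n > 0:
                contributing.append(m)
                vafs.append(v)
                alts.append(alt_n)
                refs.append(ref_n)
        row = {"branch": branch, "n_mutations": len(muts),
               "n_usable": len(usable), "n_contributing": len(contributing),
               "alt_sum": int(sum(alts)), "ref_sum": int(sum(refs))}
        if not contributing:
            row.update({"contribution": np.nan, "median_vaf": np.nan,
                        "chi2_p": np.nan, "subdivided": False, "segments": []})
        else:
            if len(contributing) >= 2:
                table = np.array([alts, refs])
                if table.sum(axis=0).min() > 0:
                    chi_p = float(stats.chi2_contingency(table)[1])
                else:
                    chi_p = np.nan
            else:
                chi_p = np.nan
            subdivided = bool(chi_p < alpha) if np.isfinite(chi_p) else False
            med = float(np.median(vafs))
            row.update({
                "median_vaf": med,
                "contribution": min(1.0, 2 * med),
                "chi2_p": chi_p,
                "subdivided": subdivided,
                "segments": [(m, min(1.0, 2 * v)) for m, v in zip(contributing, vafs)]
                if subdivided else [(branch, min(1.0, 2 * med))],
            })
        rows.append(row)
    out = pd.DataFrame(rows).set_index("branch")
    lt.contributions = out
    return out


def compare_branches(lt: LineageTree, bulk_counts: dict, branch_a: str,
                     branch_b: str, trisomy_contig: str = "chr21"):
    """Two-sided Fisher exact test on the summed (alt, ref) allele counts
    of two branches' contributing mutations."""
    sums = {}
    meta = lt.matrix.metadata
    for br in (branch_a, branch_b):
        alt = ref = 0
        n_contrib = 0
        for m in lt.branch_mutations[br]:
            if m not in bulk_counts:
                continue
            if not meta.empty and meta.loc[m, "contig"] == trisomy_contig:
                continue
            r, a = bulk_counts[m]
            if a > 0:
                alt += a
                ref += r
                n_contrib += 1
        if n_contrib == 0:
            raise ValueError(f"branch {br!r} has no contributing mutation")
        sums[br] = (alt, ref)
    table = [list(sums[branch_a]), list(sums[branch_b])]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table


# ---------------------------------------------------------------------------
# Comparison & output
# ---------------------------------------------------------------------------

def clade_sets(tree: TreeNode) -> set:
    """Non-trivial clades (leaf-name frozensets) of a rooted tree."""
    out = set()
    leaves = frozenset(l.name for l in tree.tips())
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(l.name for l in node.tips())
        if 1 < len(clade) < len(leaves):
            out.add(clade)
    return out


def rooted_rf_distance(a: TreeNode, b: TreeNode) -> int:
    """Robinson-Foulds distance between two rooted trees on the same leaves
    (symmetric difference of their non-trivial clade sets)."""
    la = frozenset(l.name for l in a.tips())
    lb = frozenset(l.name for l in b.tips())
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(clade_sets(a) ^ clade_sets(b))


def write_newick(lt: LineageTree, path, sidecar: bool = True) -> None:
    """Newick with branch lengths = mutation counts, plus a contributions
    sidecar TSV when available."""
    lt.tree.write(str(path))
    if sidecar and lt.contributions is not None:
        lt.contributions.drop(columns=["segments"], errors="ignore").to_csv(
            f"{path}.branches.tsv", sep="\t")


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))
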