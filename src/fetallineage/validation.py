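"""Seeded recovery experiments on the synthetic cohort.

Every analysis stage is exercised end-to-end against the generator's truth
labels: filter truth recovery, lineage-tree reconstruction, branch
contributions, the signature selection/bootstrap/permutation machinery and
the mixed-effects burden models.  The functions here are deterministic
given their seeds and return plain dictionaries of summary quantities, so
they serve both the test suite and the reproduction script.

Experiment designs (problem sizes, division depths, mutation densities)
are chosen so each stage's signal is identifiable at desk scale; they are
documented in docs/methods.md.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import fit_trisomy_model, leave_n_out, variance_lr_test
from .filtering import FilterConfig, call_somatic
from .lineage import (
    branch_contribution, build_tree, compare_branches, first_branches,
    parse_newick, rooted_rf_distance,
)
from .signatures import (
    SpectrumProfile, bootstrap_selection, permutation_exposure_test,
    reverse_select,
)
from .synthetic import (
    CohortConfig, SyntheticReference, bulk_allele_counts,
    dirichlet_signature_catalog, simulate_burden_table, simulate_embryo,
    truth_matrix,
)

TINY_GENOME = (("chr1", 150_000), ("chr2", 150_000), ("chr3", 150_000))


# ---------------------------------------------------------------------------
# Criterion-style experiments
# ---------------------------------------------------------------------------

def filtering_truth_recovery(seed: int = 0, n_donors_d21: int = 5,
                             n_donors_t21: int = 4, clones_per_donor: int = 5
                             ) -> dict:
    """Precision/recall of the somatic pipeline on the default cohort.

    Per-clone somatic SNV sets (clonal union shared-present) are compared
    with the generator's callable truth; germline leakage and retained
    in-vitro artifacts are tallied separately.
    """
    cfg = CohortConfig(n_donors_d21=n_donors_d21, n_donors_t21=n_donors_t21,
                       clones_per_donor=clones_per_donor, seed=seed)
    cohort = simulate_embryo(cfg)
    fcfg = FilterConfig()
    tp = fp = fn = 0
    germline_retained = 0
    invitro_retained = invitro_total = 0
    for donor in cohort.donors:
        records = donor.to_records()
        cs = call_somatic(records, donor.clones, donor.bulk_id, cohort.meta,
                          fcfg, with_indels=False)
        sets = cs.clone_sets()
        germ = donor.true_germline()
        for clone in donor.clones:
            kept = sets[clone]
            truth = donor.true_clonal_set(clone)
            iv = donor.true_invitro(clone)
            tp += len(kept & truth)
            fp += len(kept - truth)
            fn += len(truth - kept)
            germline_retained += len(kept & germ)
            invitro_retained += len(kept & iv)
            invitro_total += len(iv)
    return {
        "precision": tp / (tp + fp),
        "recall": tp / (tp + fn),
        "germline_retained": germline_retained,
        "invitro_rejection": 1.0 - invitro_retained / invitro_total,
        "n_true": tp + fn,
        "n_clones": (n_donors_d21 + n_donors_t21) * clones_per_donor,
    }


def _tree_config(seed: int) -> CohortConfig:
    return CohortConfig(
        n_donors_d21=1, n_donors_t21=0, clones_per_donor=5, mu_early=10.0,
        n_germline=0, n_invitro=0, error_rate=0.0, indels_per_clone=0.0,
        genome=TINY_GENOME, seed=seed)


def _min_branch_mutations(donor) -> int:
    v = donor.variants
    counts = {}
    for r in v[v["origin"].isin(["early", "late"])].itertuples():
        key = frozenset(r.carriers)
        counts[key] = counts.get(key, 0) + 1
    tree = parse_newick(donor.tree_newick)
    clades = [frozenset(l.name for l in n.tips()) or frozenset([n.name])
              for n in tree.traverse(include_self=False)]
    return min(counts.get(c, 0) for c in clades)


def tree_recovery(n_seeds: int = 20, seed0: int = 0,
                  reference: SyntheticReference | None = None) -> dict:
    """Robinson-Foulds distance of NJ reconstructions to the true trees.

    Replicates are conditioned on every true branch carrying at least 5
    mutations (the regime in which the topology is identifiable);
    violating draws are deterministically re-drawn.
    """
    if reference is None:
        reference = SyntheticReference(TINY_GENOME, seed=1)
    rfs = []
    for s in range(n_seeds):
        attempt = 0
        while True:
            cfg = _tree_config(seed0 + 1000 * s + attempt)
            donor = simulate_embryo(cfg, reference=reference).donors[0]
            if _min_branch_mutations(donor) >= 5:
                break
            attempt += 1
        lt = build_tree(truth_matrix(donor))
        truth = parse_newick(donor.tree_newick)
        rfs.append(rooted_rf_distance(lt.tree, truth))
    return {"max_rf": int(max(rfs)), "n_exact": int(sum(r == 0 for r in rfs)),
            "n_seeds": n_seeds}


def _contribution_config(dominance: float, seed: int) -> CohortConfig:
    return CohortConfig(
        n_donors_d21=1, n_donors_t21=0, clones_per_donor=6,
        pre_gastrulation_divisions=3, mu_early=6.0, n_germline=0,
        n_invitro=0, error_rate=0.0, indels_per_clone=0.0,
        ectoderm_dominance=dominance, genome=TINY_GENOME, seed=seed)


def branch_contribution_experiment(dominance: float, n_reps: int = 50,
                                   seed0: int = 0,
                                   reference: SyntheticReference | None = None
                                   ) -> dict:
    """Accuracy of 2 x median-VAF contributions and the first-branch
    Fisher comparison, for one ectoderm dominance setting.

    A shallow three-division embryo with six clones balanced over the
    first two lineages makes each first branch a single cell division, so
    its mutations share one true VAF and the chi-square subdivision /
    Fisher comparison are exercised in their intended regime.
    """
    if reference is None:
        reference = SyntheticReference(TINY_GENOME, seed=1)
    errors, fisher_sig = [], []
    for rep in range(n_reps):
        attempt = 0
        while True:
            cfg = _contribution_config(dominance, seed0 + 1000 * rep + attempt)
            donor = simulate_embryo(cfg, reference=reference).donors[0]
            tree = parse_newick(donor.tree_newick)
            kids = [frozenset(l.name for l in c.tips())
                    for c in tree.children]
            truth_fracs = {
                frozenset(r.branch_clones.split(",")): r.true_cell_fraction
                for r in donor.branch_truth.itertuples()}
            fracs = [truth_fracs.get(k) for k in kids]
            if len(kids) != 2 or None in fracs or \
                    abs(sum(fracs) - 1.0) > 1e-9:
                attempt += 1    # a first-division edge carries no mutation
                continue
            lt = build_tree(truth_matrix(donor))
            counts = bulk_allele_counts(donor)
            fb = first_branches(lt)
            try:
                p, _ = compare_branches(lt, counts, fb[0], fb[1])
            except ValueError:
                attempt += 1    # minority branch invisible in bulk reads
                continue
            break
        contrib = branch_contribution(lt, counts)
        clade_of = {}
        for name in fb:
            node = lt.tree.find(name)
            clade_of[name] = frozenset(l.name for l in node.tips()) \
                or frozenset([name])
        for name in fb:
            est = contrib.loc[name, "contribution"]
            if np.isfinite(est):
                errors.append(abs(est - truth_fracs[clade_of[name]]))
        fisher_sig.append(p < 0.05)
    return {
        "median_abs_error": float(np.median(errors)),
        "fisher_significant_fraction": float(np.mean(fisher_sig)),
        "n_reps": n_reps,
    }


def signature_selection_experiment(seed: int = 0, n_mut: int = 1000,
                                   n_boot: int = 200) -> dict:
    """Reverse selection and its bootstrap on an exact two-signature
    mixture hidden among ten candidates."""
    catalog = dirichlet_signature_catalog(10, seed=7)
    true = ["SIG3", "SIG8"]
    mix = 0.6 * catalog.matrix["SIG3"].to_numpy() \
        + 0.4 * catalog.matrix["SIG8"].to_numpy()
    exact = SpectrumProfile("exact", n_mut * mix)
    sel = reverse_select([exact], catalog)
    rng = np.random.default_rng(seed)
    noisy = SpectrumProfile("noisy", rng.multinomial(n_mut, mix).astype(float))
    bs = bootstrap_selection([noisy], catalog, n_boot=n_boot, seed=seed + 1)
    freq = bs.selection_frequency
    return {
        "selection_exact": sorted(sel.selected) == sorted(true),
        "true_min_frequency": float(freq[true].min()),
        "false_max_frequency": float(freq.drop(true).max()),
        "n_boot": n_boot,
    }


def permutation_type1(n_runs: int = 200, n_perm: int = 500,
                      seed0: int = 0) -> dict:
    """Type-I error of the fixed-margin permutation test: both categories
    drawn from one signature mixture."""
    catalog = dirichlet_signature_catalog(10, seed=7)
    sigs = ["SIG3", "SIG8"]
    mix = 0.6 * catalog.matrix["SIG3"].to_numpy() \
        + 0.4 * catalog.matrix["SIG8"].to_numpy()
    rej = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed0 + run)
        a = rng.multinomial(500, mix).astype(float)
        b = rng.multinomial(500, mix).astype(float)
        cm = pd.DataFrame([a, b], index=["a", "b"])
        p = permutation_exposure_test(cm, catalog, sigs, n_perm=n_perm,
                                      seed=seed0 + run)
        rej += p.loc["a", "SIG3"] < 0.05
    return {"rejection_rate": rej / n_runs, "n_runs": n_runs,
            "n_perm": n_perm}


def trisomy_recovery(n_reps: int = 100, excess: float = 34.0,
                     seed0: int = 0) -> dict:
    """Coverage of the 95% CI for a simulated trisomy excess under the
    paper-shaped design (5 + 4 donors, 5 clones each)."""
    covered = 0
    estimates = []
    for rep in range(n_reps):
        df = simulate_burden_table(seed=seed0 + rep, trisomy_excess=excess)
        res = fit_trisomy_model(df)
        lo, hi = res.conf_int.loc["trisomy21"]
        covered += lo <= excess <= hi
        estimates.append(res.params["trisomy21"])
    return {"coverage": covered / n_reps, "mean_estimate": float(np.mean(estimates)),
            "n_reps": n_reps, "true_excess": excess}


def null_calibration(n_reps: int = 200, seed0: int = 10_000) -> dict:
    """Rejection rate of the trisomy contrast when no excess is simulated."""
    rej = 0
    for rep in range(n_reps):
        df = simulate_burden_table(seed=seed0 + rep, trisomy_excess=0.0)
        res = fit_trisomy_model(df)
        rej += res.pvalues["trisomy21"] < 0.05
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


def lr_calibration(n_reps: int = 200, seed0: int = 20_000) -> dict:
    """Rejection rate of the variance LR test under equal group variances."""
    rej = 0
    for rep in range(n_reps):
        df = simulate_burden_table(seed=seed0 + rep, trisomy_excess=0.0)
        _, p = variance_lr_test(df)
        rej += p < 0.05
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


def leave_n_out_strong_effect(seed: int = 0) -> dict:
    """Max leave-1-out and leave-2-out p-values for a strong simulated
    excess (60 extra mutations, low noise)."""
    df = simulate_burden_table(seed=seed, trisomy_excess=60.0,
                               donor_slope_sd=5.0, resid_sd_d21=4.0,
                               resid_sd_t21=4.0)
    out = {}
    for n in (1, 2):
        res = leave_n_out(df, n, fit_trisomy_model, effects=["trisomy21"])
        out[f"max_p_leave_{n}"] = res.attrs["max_p"]["p[trisomy21]"]
        out[f"n_fits_leave_{n}"] = len(res)
    return out
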