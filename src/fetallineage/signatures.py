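"""Mutational-spectrum construction and signature refitting.

The workhorse here is non-negative least-squares (NNLS) refitting of
96-channel mutation spectra against a column-stochastic signature catalog,
wrapped in the selection/uncertainty machinery used for low-burden samples:

* iterative *reverse selection* that discards the signature with the lowest
  summed exposure until the reconstruction cosine similarity drops by more
  than a cutoff between consecutive iterations;
* a bootstrap (multinomial resampling of each profile) that yields
  per-signature selection frequencies and exposure distributions, whose
  pairwise correlations diagnose collinear signatures;
* a fixed-margin permutation test comparing relative signature exposures
  between categories.

Exposures are expressed in mutation counts throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .contexts import CONTEXTS_96, CONTEXT_INDEX, trinucleotide_context


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectrumProfile:
    """A 96-channel count vector for one sample category."""

    label: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (96,):
            raise ValueError("a spectrum has exactly 96 channels")
        if (counts < 0).any():
            raise ValueError("channel counts must be non-negative")
        self.counts = counts

    @property
    def n_mutations(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_96), name=self.label)


class SignatureCatalog:
    """A 96 x S column-stochastic reference signature matrix."""

    def __init__(self, matrix: pd.DataFrame):
        if matrix.shape[0] != 96:
            raise ValueError(f"catalog must have 96 context rows, got {matrix.shape[0]}")
        if set(matrix.index) != set(CONTEXTS_96):
            raise ValueError("catalog rows must be the 96 canonical contexts")
        if (matrix.values < 0).any():
            raise ValueError("catalog entries must be non-negative")
        matrix = matrix.reindex(list(CONTEXTS_96)).astype(float)
        sums = matrix.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("catalog columns must have positive mass")
        self.matrix = matrix / sums
        self.names = list(matrix.columns)

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"signatures not in catalog: {missing}")
        return SignatureCatalog(self.matrix[list(names)])

    def values(self, names: Sequence[str] | None = None) -> np.ndarray:
        cols = self.names if names is None else list(names)
        return self.matrix[cols].to_numpy()

    def concat(self, other: "SignatureCatalog") -> "SignatureCatalog":
        return SignatureCatalog(pd.concat([self.matrix, other.matrix], axis=1))


@dataclass
class RefitResult:
    exposures: pd.Series          # mutation counts per signature
    cosine: float
    reconstruction: np.ndarray
    selected: list = field(default_factory=list)
    trace: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------

def build_spectrum(mutations, fasta, category: str,
                   donor_map: Mapping[str, str] | None = None) -> SpectrumProfile:
    """Pool SNVs of one category into a 96-channel spectrum.

    ``mutations`` is an iterable of ``(sample, contig, pos, ref, alt)``
    tuples.  A mutation recurring in several clones of the same donor is
    counted once (``donor_map`` maps sample -> donor; without it each sample
    is its own donor).  Variants whose context cannot be resolved are
    skipped.
    """
    counts = np.zeros(96)
    seen = set()
    skipped = 0
    for sample, contig, pos, ref, alt in mutations:
        donor = donor_map.get(sample, sample) if donor_map else sample
        key = (donor, contig, pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        try:
            ch = trinucleotide_context(fasta, contig, pos, ref, alt)
        except ValueError:
            skipped += 1
            continue
        counts[CONTEXT_INDEX[ch]] += 1
    profile = SpectrumProfile(category, counts)
    profile.n_skipped = skipped
    return profile


def compare_spectra(a: SpectrumProfile, b: SpectrumProfile):
    """Chi-square test on the 2 x 96 contingency table of two spectra.

    Channels with zero counts in both spectra are dropped.  Returns
    ``(statistic, p)``.
    """
    if a.n_mutations == 0 or b.n_mutations == 0:
        raise ValueError("cannot compare an empty spectrum")
    table = np.vstack([a.counts, b.counts])
    keep = table.sum(axis=0) > 0
    stat, p, _, _ = stats.chi2_contingency(table[:, keep])
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Refitting
# ---------------------------------------------------------------------------

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


def refit_nnls(profile: SpectrumProfile, catalog: SignatureCatalog,
               names: Sequence[str] | None = None) -> RefitResult:
    """Non-negative least-squares refit of one profile against a catalog."""
    cols = list(catalog.names if names is None else names)
    if not cols:
        raise ValueError("signature set is empty")
    A = catalog.values(cols)
    x, _ = optimize.nnls(A, profile.counts)
    recon = A @ x
    return RefitResult(
        exposures=pd.Series(x, index=cols),
        cosine=_cosine(profile.counts, recon),
        reconstruction=recon,
        selected=cols,
    )


@dataclass
class SelectionResult:
    selected: list
    trace: pd.DataFrame
    fits: list          # RefitResult per profile, on the selected set


def _joint_fit(profiles, catalog, names):
    fits = [refit_nnls(p, catalog, names) for p in profiles]
    mean_cos = float(np.mean([f.cosine for f in fits]))
    total = sum((f.exposures for f in fits), pd.Series(0.0, index=list(names)))
    return fits, mean_cos, total


def reverse_select(profiles: Sequence[SpectrumProfile], catalog: SignatureCatalog,
                   cutoff: float = 0.05) -> SelectionResult:
    """Iterative reverse signature selection.

    All profiles are fitted jointly against the current signature set; the
    signature with the lowest summed exposure across profiles is removed;
    iteration stops when the mean reconstruction cosine similarity drops by
    more than ``cutoff`` between two consecutive iterations, returning the
    set held before the violating removal.  With a cutoff that never
    triggers the process runs down to a single signature.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not profiles:
        raise ValueError("need at least one profile")
    current = list(catalog.names)
    fits, cos, total = _joint_fit(profiles, catalog, current)
    rows = [{"iteration": 0, "n_signatures": len(current), "removed": None,
             "mean_cosine": cos}]
    it = 0
    while len(current) > 1:
        # remove the lowest total exposure; ties broken by column order
        drop = total.index[int(np.argmin(total.to_numpy()))]
        candidate = [n for n in current if n != drop]
        new_fits, new_cos, new_total = _joint_fit(profiles, catalog, candidate)
        it += 1
        rows.append({"iteration": it, "n_signatures": len(candidate),
                     "removed": drop, "mean_cosine": new_cos})
        if cos - new_cos > cutoff:
            trace = pd.DataFrame(rows)
            trace.loc[trace.index[-1], "rejected"] = True
            return SelectionResult(selected=current, trace=trace, fits=fits)
        current, fits, cos, total = candidate, new_fits, new_cos, new_total
    return SelectionResult(selected=current, trace=pd.DataFrame(rows), fits=fits)


def constrained_refit(profiles: Sequence[SpectrumProfile], catalog: SignatureCatalog,
                      fixed_signatures: Sequence[str]) -> list[RefitResult]:
    """Plain NNLS of each profile against a fixed signature set (no selection)."""
    fixed = list(fixed_signatures)
    if not fixed:
        raise ValueError("fixed signature set is empty")
    return [refit_nnls(p, catalog, fixed) for p in profiles]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    selection_frequency: pd.Series       # fraction of iterations selecting each signature
    exposures: pd.DataFrame              # n_boot x S total exposures (0 when unselected)
    exposure_quantiles: pd.DataFrame
    exposure_correlation: pd.DataFrame   # collinearity diagnostic
    n_boot: int

    def selected_at(self, threshold: float = 0.5) -> list:
        return [s for s in self.selection_frequency.index
                if self.selection_frequency[s] >= threshold]


def bootstrap_selection(profiles: Sequence[SpectrumProfile], catalog: SignatureCatalog,
                        n_boot: int = 1000, seed=None,
                        cutoff: float = 0.05) -> BootstrapResult:
    """Bootstrap of the reverse-selection refit.

    Each iteration resamples every profile's mutations with replacement
    (a multinomial of its own size over its empirical channel frequencies),
    reruns :func:`reverse_select`, and records the selected set together
    with the summed exposures over profiles.  Signatures not selected in an
    iteration contribute exposure 0.
    """
    rng = np.random.default_rng(seed)
    names = list(catalog.names)
    sel = np.zeros((n_boot, len(names)))
    exp = np.zeros((n_boot, len(names)))
    for b in range(n_boot):
        boot_profiles = []
        for p in profiles:
            n = int(round(p.n_mutations))
            if n == 0:
                boot_profiles.append(SpectrumProfile(p.label, np.zeros(96)))
                continue
            freqs = p.counts / p.counts.sum()
            boot_profiles.append(
                SpectrumProfile(p.label, rng.multinomial(n, freqs).astype(float)))
        res = reverse_select(boot_profiles, catalog, cutoff=cutoff)
        total = sum((f.exposures for f in res.fits),
                    pd.Series(0.0, index=res.selected))
        for name in res.selected:
            j = names.index(name)
            sel[b, j] = 1.0
            exp[b, j] = total[name]
    freq = pd.Series(sel.mean(axis=0), index=names, name="selection_frequency")
    exposures = pd.DataFrame(exp, columns=names)
    quantiles = exposures.quantile([0.025, 0.25, 0.5, 0.75, 0.975])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = exposures.corr()
    return BootstrapResult(freq, exposures, quantiles, corr, n_boot)


# ---------------------------------------------------------------------------
# Fixed-margin permutation test
# ---------------------------------------------------------------------------

def _relative_exposures(counts: np.ndarray, A: np.ndarray) -> np.ndarray:
    x, _ = optimize.nnls(A, counts)
    tot = x.sum()
    return x / tot if tot > 0 else x


def permutation_exposure_test(count_matrix: pd.DataFrame, catalog: SignatureCatalog,
                              signatures: Sequence[str], n_perm: int = 2000,
                              seed=None) -> pd.DataFrame:
    """Fixed-margin permutation test of relative signature exposures.

    ``count_matrix`` is a categories x 96 table of channel counts.  Random
    tables with the observed row and column margins are drawn
    (Patefield sampling via :func:`scipy.stats.random_table`); each permuted
    row is refitted by NNLS against ``signatures`` and the two-tailed
    p-value per (category, signature) is twice the smaller tail frequency,
    floored at ``2 / n_perm`` and capped at 1.
    """
    if count_matrix.shape[0] < 2:
        raise ValueError("permutation test needs at least two category rows")
    if count_matrix.shape[1] != 96:
        raise ValueError("count matrix must have 96 channel columns")
    counts = count_matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    if (row_margins == 0).any():
        raise ValueError("degenerate margins: a category row sums to zero")
    sigs = list(signatures)
    if not sigs:
        raise ValueError("empty signature set")
    A = catalog.values(sigs)

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_margins, col_margins)
    tables = sampler.rvs(n_perm, random_state=rng)
    tables = tables.reshape(n_perm, *counts.shape)
    # margin preservation is a hard invariant of the sampler
    assert np.allclose(tables.sum(axis=2), row_margins)
    assert np.allclose(tables.sum(axis=1), col_margins)

    observed = np.vstack([_relative_exposures(counts[i], A)
                          for i in range(counts.shape[0])])
    perms = np.empty((n_perm, counts.shape[0], len(sigs)))
    for b in range(n_perm):
        for i in range(counts.shape[0]):
            perms[b, i] = _relative_exposures(tables[b, i], A)

    ge = (perms >= observed[None, :, :] - 1e-12).mean(axis=0)
    le = (perms <= observed[None, :, :] + 1e-12).mean(axis=0)
    p = 2.0 * np.minimum(ge, le)
    p = np.clip(p, 2.0 / n_perm, 1.0)
    out = pd.DataFrame(p, index=count_matrix.index, columns=sigs)
    out.attrs["n_perm"] = n_perm
    return out


# ---------------------------------------------------------------------------
# Raw DBS / indel tallies (no COSMIC DBS-78 / ID-83 classification)
# ---------------------------------------------------------------------------

def tally_dbs_changes(dbs_pairs: Iterable[tuple[str, str]]) -> pd.Series:
    """Raw dinucleotide-change tallies, e.g. ('CT','AA') -> 'CT>AA'."""
    out: dict[str, int] = {}
    for ref2, alt2 in dbs_pairs:
        key = f"{ref2}>{alt2}"
        out[key] = out.get(key, 0) + 1
    return pd.Series(out, dtype=int).sort_index()


def tally_indel_lengths(indels: Iterable[tuple[str, str]]) -> pd.Series:
    """Signed indel-length tallies (positive insertion, negative deletion)."""
    out: dict[int, int] = {}
    for ref, alt in indels:
        delta = len(alt) - len(ref)
        out[delta] = out.get(delta, 0) + 1
    return pd.Series(out, dtype=int).sort_index()
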