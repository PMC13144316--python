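"""SBS96 mutational-signature extraction and cohort exposure comparison.

Single-base substitutions are classified into the 96 pyrimidine-centered
trinucleotide classes (purine-reference changes are reverse-complemented)
and accumulated into a sample x 96 catalog.  De novo signatures are
extracted by non-negative matrix factorization with the KL-divergence
objective (natural for count data) under a resampling scheme: for each
candidate signature number k, the catalog is Poisson-resampled
``n_replicates`` times, each replicate is factorized from a distinct
seeded initialization, the pooled replicate signatures are clustered into
k groups by cosine distance (Hungarian matching of each replicate to the
running consensus), and cluster tightness (mean silhouette) is the
stability of that k.  The consensus signatures are cluster medoids;
exposures are refit per sample by non-negative least squares on the
original catalog.  The selected k is the largest candidate whose
stability reaches the floor (default 0.8), ties broken toward lower mean
reconstruction cosine distance; if no candidate reaches the floor, the
highest-stability candidate wins.

Consensus signatures are then decomposed onto a reference spectra matrix
(COSMIC-style) by NNLS; the contribution percentages name each signature
after its top reference.  Per-signature exposures are compared between
cohorts with two-sided Mann-Whitney tests (absolute attributed counts by
default; a proportion mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import SBS96_CLASSES, VariantRecord
from .stats import cosine_similarity, mann_whitney_u, nnls

__all__ = [
    "SignatureModel",
    "DecompositionResult",
    "build_catalog",
    "extract_signatures",
    "decompose_to_reference",
    "compare_exposures",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CLASS_INDEX = {c: i for i, c in enumerate(SBS96_CLASSES)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def sbs96_class(ref: str, alt: str, context: str) -> str:
    """The SBS96 class of a substitution given its reference-strand 3-mer.

    The context's middle base must equal the reference allele; purine
    references are reverse-complemented to the pyrimidine-centered class.
    """
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"bad trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref allele {ref!r}")
    if ref in ("A", "G"):
        context = _revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_catalog(
    variants: Sequence[VariantRecord],
    fasta: "object | None" = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Accumulate SNVs into a sample x 96 count catalog.

    Context comes from each record's ``trinucleotide_context`` column, or —
    when absent and ``fasta`` (a ``pyfaidx.Fasta``-like mapping) is given —
    from the reference sequence around the position.  Non-SNV records are
    skipped and counted; records with unknown bases are skipped with a
    count.  Returns the catalog (COSMIC column order) and a skip-count
    dict.
    """
    counts: dict[str, np.ndarray] = {}
    skipped = {"non_snv": 0, "no_context": 0, "unknown_base": 0}
    for v in variants:
        if not v.is_snv:
            skipped["non_snv"] += 1
            continue
        context = v.trinucleotide_context
        if context is None:
            if fasta is None:
                skipped["no_context"] += 1
                continue
            seq = fasta[v.chromosome][v.position - 1 : v.position + 2]
            context = str(seq).upper()
        if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
            skipped["unknown_base"] += 1
            continue
        if context[1] != v.ref_allele:
            raise ValueError(
                f"context/ref mismatch at {v.chromosome}:{v.position + 1}: "
                f"context {context!r} vs ref {v.ref_allele!r}"
            )
        cls = sbs96_class(v.ref_allele, v.alt_allele, context)
        row = counts.setdefault(v.sample_id, np.zeros(96, dtype=np.int64))
        row[_CLASS_INDEX[cls]] += 1
    catalog = pd.DataFrame.from_dict(counts, orient="index", columns=list(SBS96_CLASSES))
    catalog = catalog.sort_index(kind="mergesort")
    return catalog, skipped


# ---------------------------------------------------------------------------
# NMF with KL objective


def _kl_loop_impl(V, W, H, max_iter, tol, check_every):  # pragma: no cover - thin kernel
    eps = 1e-12
    m, k = W.shape
    n = H.shape[1]
    prev = np.inf
    for it in range(1, max_iter + 1):
        WH = np.dot(W, H)
        R = V / (WH + eps)
        RH = np.dot(R, H.T)
        for t in range(k):
            s = eps
            for j in range(n):
                s += H[t, j]
            for i in range(m):
                w = W[i, t] * RH[i, t] / s
                # floor keeps the multiplicative updates positive and the
                # entries out of the subnormal range (which is very slow)
                W[i, t] = w if w > 1e-30 else 1e-30
        WH = np.dot(W, H)
        R = V / (WH + eps)
        WR = np.dot(W.T, R)
        for t in range(k):
            s = eps
            for i in range(m):
                s += W[i, t]
            for j in range(n):
                h = H[t, j] * WR[t, j] / s
                H[t, j] = h if h > 1e-30 else 1e-30
        if it % check_every == 0 or it == max_iter:
            WH = np.dot(W, H)
            obj = 0.0
            for i in range(m):
                for j in range(n):
                    wh = WH[i, j] + eps
                    v = V[i, j]
                    obj += v * np.log((v + eps) / wh) - v + wh
            denom = 1.0
            if np.isfinite(prev) and prev != 0.0:
                denom = abs(prev)
            if abs(prev - obj) / denom < tol:
                return it
            prev = obj
    return max_iter


try:  # compiled kernel when numba is available; semantics identical
    from numba import njit

    _kl_loop = njit(cache=True)(_kl_loop_impl)
except ImportError:  # pragma: no cover
    _kl_loop = _kl_loop_impl


def _nmf_kl(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    check_every: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing generalized KL divergence.

    V is 96 x n_samples; returns W (96 x k, columns sum to 1) and H
    (k x n_samples) with W @ H approximating V.  Convergence: relative
    change of the KL objective below ``tol`` between checks, or
    ``max_iter`` sweeps.
    """
    m, n = V.shape
    scale = V.mean()
    W = rng.uniform(0.1, 1.0, size=(m, k)) * np.sqrt(scale / k)
    H = rng.uniform(0.1, 1.0, size=(k, n)) * np.sqrt(scale / k)
    _kl_loop(np.ascontiguousarray(V, dtype=np.float64), W, H, max_iter, tol, check_every)
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    return W / col, H * col[:, None]


def _cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between columns of A and columns of B."""
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return 1.0 - An.T @ Bn


def _silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of column vectors under cosine distance.

    For a single cluster, stability is instead the mean cosine similarity
    of members to their mean direction (1 = perfectly reproducible).
    """
    k = labels.max() + 1
    D = _cosine_distance_matrix(points, points)
    n = points.shape[1]
    if k == 1:
        if n < 2:
            return 1.0
        off = D[~np.eye(n, dtype=bool)]
        return float(1.0 - off.mean())
    scores = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        a = D[i, same].mean() if same.any() else 0.0
        b = min(D[i, labels == other].mean() for other in range(k) if other != own and (labels == other).any())
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(scores.mean())


@dataclass
class SignatureModel:
    """Consensus signatures, exposures and model-selection diagnostics."""

    k: int
    signatures: pd.DataFrame  # 96 x k, columns sum to 1
    exposures: pd.DataFrame  # k x samples, attributed mutation counts
    diagnostics: pd.DataFrame  # per candidate k: stability, reconstruction
    seed: int | None
    n_replicates: int

    def reconstruction(self) -> pd.DataFrame:
        recon = self.signatures.values @ self.exposures.values
        return pd.DataFrame(recon, index=self.signatures.index, columns=self.exposures.columns)


def _extract_for_k(
    V: np.ndarray,
    k: int,
    n_replicates: int,
    resample: str,
    rng: np.random.Generator,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Replicate NMF runs, clustering, consensus and diagnostics for one k."""
    from scipy.optimize import linear_sum_assignment

    replicate_sigs: list[np.ndarray] = []
    for _ in range(n_replicates):
        if resample == "poisson":
            Vr = rng.poisson(V).astype(float)
            if Vr.sum() == 0:
                Vr = V.copy()
        elif resample == "none":
            Vr = V
        else:
            raise ValueError(f"unknown resample scheme {resample!r}")
        W, _ = _nmf_kl(Vr, k, rng, max_iter=max_iter)
        replicate_sigs.append(W)

    # cluster pooled signatures: Hungarian-match each replicate to the
    # running consensus means, one signature per cluster per replicate
    centers = replicate_sigs[0].copy()
    members: list[list[np.ndarray]] = [[centers[:, j].copy()] for j in range(k)]
    for W in replicate_sigs[1:]:
        D = _cosine_distance_matrix(centers, W)
        rows, cols = linear_sum_assignment(D)
        for j, c in zip(rows, cols):
            members[j].append(W[:, c])
            stacked = np.column_stack(members[j])
            centers[:, j] = stacked.mean(axis=1)

    points = np.column_stack([sig for group in members for sig in group])
    labels = np.concatenate([[j] * len(group) for j, group in enumerate(members)])
    stability = _silhouette(points, labels)

    # medoid = member minimizing total cosine distance to its cluster
    consensus = np.empty((V.shape[0], k))
    for j, group in enumerate(members):
        stacked = np.column_stack(group)
        D = _cosine_distance_matrix(stacked, stacked)
        consensus[:, j] = stacked[:, int(np.argmin(D.sum(axis=0)))]
    consensus /= consensus.sum(axis=0, keepdims=True)

    H = np.column_stack([nnls(consensus, V[:, s]) for s in range(V.shape[1])])
    recon = consensus @ H
    dists = []
    for s in range(V.shape[1]):
        if V[:, s].sum() == 0 or recon[:, s].sum() == 0:
            continue
        dists.append(1.0 - cosine_similarity(V[:, s], recon[:, s]))
    recon_dist = float(np.mean(dists)) if dists else 1.0
    return consensus, H, stability, recon_dist


def extract_signatures(
    catalog: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 10,
    n_replicates: int = 20,
    resample: str = "poisson",
    seed: int | None = None,
    stability_floor: float = 0.8,
    max_iter: int = 10_000,
) -> SignatureModel:
    """De novo signature extraction with stability-based selection of k."""
    if list(catalog.columns) != list(SBS96_CLASSES):
        raise ValueError("catalog columns must be the 96 SBS classes in COSMIC order")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    V = catalog.values.T.astype(float)  # 96 x samples
    if V.sum() == 0:
        raise ValueError("catalog is all zeros")
    if not (1 <= k_min <= k_max):
        raise ValueError(f"bad k range [{k_min}, {k_max}]")
    k_max = min(k_max, V.shape[1])

    rng = np.random.default_rng(seed)
    results: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    diag_rows = []
    for k in range(k_min, k_max + 1):
        W, H, stability, recon = _extract_for_k(V, k, n_replicates, resample, rng, max_iter)
        results[k] = (W, H)
        diag_rows.append({"k": k, "stability": stability, "reconstruction_cosine_distance": recon})
    diagnostics = pd.DataFrame(diag_rows).set_index("k")

    stable = diagnostics[diagnostics["stability"] >= stability_floor]
    if not stable.empty:
        selected = int(stable.index.max())
    else:
        best = diagnostics.sort_values(
            ["stability", "reconstruction_cosine_distance"], ascending=[False, True], kind="mergesort"
        )
        selected = int(best.index[0])

    W, H = results[selected]
    sig_names = [f"SBS96{chr(ord('A') + i)}" for i in range(selected)]
    signatures = pd.DataFrame(W, index=list(SBS96_CLASSES), columns=sig_names)
    exposures = pd.DataFrame(H, index=sig_names, columns=list(catalog.index))
    return SignatureModel(
        k=selected,
        signatures=signatures,
        exposures=exposures,
        diagnostics=diagnostics,
        seed=seed,
        n_replicates=n_replicates,
    )


@dataclass(frozen=True)
class DecompositionResult:
    signature: str
    contributions: pd.Series  # percentages over reference signatures, sum 100
    assigned_reference: str
    best_single_cosine: float


def decompose_to_reference(model: SignatureModel, reference: pd.DataFrame) -> list[DecompositionResult]:
    """NNLS decomposition of each consensus signature onto reference spectra.

    Contribution percentages are the normalized NNLS coefficients; the
    assignment is the reference with the highest relative contribution.
    Also reports the cosine to the single most similar reference.
    """
    if list(reference.index) != list(SBS96_CLASSES):
        raise ValueError("reference must be indexed by the 96 SBS classes in COSMIC order")
    A = reference.values
    out = []
    for name in model.signatures.columns:
        b = model.signatures[name].values
        coef = nnls(A, b)
        total = coef.sum()
        if total == 0:
            pct = pd.Series(0.0, index=reference.columns)
        else:
            pct = pd.Series(coef / total * 100.0, index=reference.columns)
        cosines = [cosine_similarity(b, A[:, j]) for j in range(A.shape[1])]
        out.append(
            DecompositionResult(
                signature=name,
                contributions=pct,
                assigned_reference=str(pct.idxmax()),
                best_single_cosine=float(max(cosines)),
            )
        )
    return out


def compare_exposures(
    model: SignatureModel,
    cohort_labels: pd.Series,
    mode: str = "counts",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney comparison of per-sample exposures by cohort.

    ``counts`` compares absolute attributed mutation counts; ``proportions``
    first normalizes each sample's exposures to sum 1.
    """
    if mode not in ("counts", "proportions"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = set(model.exposures.columns) - set(cohort_labels.index)
    if missing:
        raise ValueError(f"samples without cohort label: {sorted(missing)[:5]}")
    labels = cohort_labels.loc[list(model.exposures.columns)]
    cohorts = sorted(labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    expo = model.exposures
    if mode == "proportions":
        totals = expo.sum(axis=0).replace(0, 1.0)
        expo = expo / totals
    rows = []
    for sig in expo.index:
        x = expo.loc[sig, labels[labels == ca].index].values.astype(float)
        y = expo.loc[sig, labels[labels == cb].index].values.astype(float)
        r = mann_whitney_u(x, y, mode="normal")
        rows.append(
            {
                "signature": sig,
                f"median_{ca}": float(np.median(x)),
                f"median_{cb}": float(np.median(y)),
                "u_statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.p_value < alpha,
                "higher_cohort": ca if np.median(x) > np.median(y) else (cb if np.median(y) > np.median(x) else ""),
            }
        )
    return pd.DataFrame(rows).set_index("signature")
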