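"""Structural-ensemble analysis: superposition, RMSF, contacts, TM-score.

Analysis is Cα-only throughout.  An :class:`Ensemble` holds M conformations
of the same chain-labelled residue set; the operations quantify which parts
of a complex are rigid and which are flexible:

* :func:`kabsch_superpose` — closed-form least-squares rigid fit (SVD with
  proper-rotation correction).
* :func:`rmsf` — per-residue root-mean-square fluctuation about the
  iteratively refined mean structure.
* :func:`contact_frequency` — fraction of models in which two residues'
  Cα atoms are within a cutoff (default 8 Å), mapping transient interface
  contacts.
* :func:`tm_score` — length-normalized fold similarity in (0, 1] against a
  reference, with the standard d0 normalization and iterative
  distance-threshold refinement; > 0.5 indicates the same fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Ensemble",
    "Superposition",
    "ContactMap",
    "kabsch_superpose",
    "rmsf",
    "contact_frequency",
    "tm_score",
    "fold_consistency",
]


@dataclass
class Ensemble:
    """Ordered conformations of one chain-labelled residue set.

    ``coords`` has shape (M, N, 3): M models, N residues (all chains
    concatenated in chain order), Cα coordinates in Å.
    """

    chains: tuple[str, ...]
    residues: tuple[tuple[str, int], ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one conformation")
        if self.coords.shape[1] != len(self.residues):
            raise ValueError("coords second axis must match residue count")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def chain_indices(self, chain: str) -> np.ndarray:
        """Indices (into the residue axis) belonging to one chain."""
        idx = np.array(
            [i for i, (c, _) in enumerate(self.residues) if c == chain],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"chain {chain!r} not present in ensemble")
        return idx


@dataclass
class Superposition:
    """A proper rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ContactMap:
    rows: tuple[tuple[str, int], ...]
    cols: tuple[tuple[str, int], ...]
    freq: np.ndarray
    cutoff: float


def kabsch_superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Superposition:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` (Kabsch).

    Returns the proper rotation (det = +1, enforced by a sign flip of the
    smallest singular vector) and translation minimizing the (weighted)
    RMSD.  Requires ≥ 3 non-collinear points.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must both have shape (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mov_c = mov - (w[:, None] * mov).sum(axis=0)
    for label, x in (("reference", ref_c), ("mobile", mov_c)):
        if np.linalg.matrix_rank(x, tol=1e-9) < 2:
            raise ValueError(f"{label} points are collinear or coincident")
    h = mov_c.T @ (w[:, None] * ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    fitted = mov_c @ rotation.T
    rmsd = float(np.sqrt((w[:, None] * (fitted - ref_c) ** 2).sum()))
    ref_centroid = (w[:, None] * ref).sum(axis=0)
    mov_centroid = (w[:, None] * mov).sum(axis=0)
    translation = ref_centroid - rotation @ mov_centroid
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def _superpose_ensemble(
    coords: np.ndarray, target: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    out = np.empty_like(coords)
    for m in range(coords.shape[0]):
        sup = kabsch_superpose(target[fit_idx], coords[m, fit_idx])
        out[m] = sup.apply(coords[m])
    return out


def rmsf(
    ensemble: Ensemble,
    fit_selection: Optional[Sequence[int]] = None,
    n_refine: int = 2,
) -> np.ndarray:
    """Per-residue Cα RMSF (Å) about the iterative mean structure.

    Each conformation is superposed onto the running mean using the
    ``fit_selection`` residues (default: all), with ``n_refine`` mean
    refinement passes.  RMSF_i = sqrt(mean_m |x_mi − x̄_i|²).
    """
    if ensemble.n_models < 2:
        raise ValueError("RMSF requires at least 2 conformations")
    fit_idx = (
        np.arange(ensemble.n_residues)
        if fit_selection is None
        else np.asarray(fit_selection, dtype=int)
    )
    fitted = _superpose_ensemble(ensemble.coords, ensemble.coords[0], fit_idx)
    for _ in range(n_refine):
        mean = fitted.mean(axis=0)
        fitted = _superpose_ensemble(fitted, mean, fit_idx)
    mean = fitted.mean(axis=0)
    return np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))


def contact_frequency(
    ensemble: Ensemble, chain_a: str, chain_b: str, cutoff: float = 8.0
) -> ContactMap:
    """Inter-chain Cα–Cα contact frequency across the ensemble.

    ``freq[i, j]`` is the fraction of models in which residue i of
    ``chain_a`` and residue j of ``chain_b`` are within ``cutoff`` Å.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = ensemble.chain_indices(chain_a)
    ib = ensemble.chain_indices(chain_b)
    m = ensemble.n_models
    counts = np.zeros((ia.size, ib.size))
    for k in range(m):
        d = cdist(ensemble.coords[k, ia], ensemble.coords[k, ib])
        counts += d <= cutoff
    return ContactMap(
        rows=tuple(ensemble.residues[i] for i in ia),
        cols=tuple(ensemble.residues[j] for j in ib),
        freq=counts / m,
        cutoff=cutoff,
    )


def tm_d0(l_target: int) -> float:
    """The TM-score distance normalization d0 = 1.24·(L−15)^(1/3) − 1.8."""
    if l_target < 16:
        raise ValueError("TM-score requires a reference of at least 16 residues")
    return 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8


def tm_score(
    model: np.ndarray,
    reference: np.ndarray,
    correspondence: Optional[np.ndarray] = None,
) -> float:
    """TM-score of ``model`` against ``reference`` over a 1:1 correspondence.

    TM = max over rigid superpositions of (1/L_t)·Σ_i 1/(1 + (d_i/d0)²),
    normalized by the reference length L_t, with
    d0 = 1.24·(L_t − 15)^(1/3) − 1.8.  The maximization follows the
    standard iterative scheme: initial Kabsch fits on the full
    correspondence and on sliding fragments of length L, L/2 and L/4;
    for each seed, residues within a distance threshold (starting at
    d0 + 1 Å, shrinking by 0.5 Å to a floor of 1.5 Å) are refit until the
    retained set repeats; the best score over all fits is kept.

    ``correspondence`` is an (L, 2) array of (model index, reference
    index) pairs; ``None`` means identity (equal lengths required).  The
    alignment itself is an input — no structural alignment search.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    l_t = reference.shape[0]
    d0 = tm_d0(l_t)
    if correspondence is None:
        if model.shape[0] != l_t:
            raise ValueError(
                "correspondence required when model and reference lengths differ"
            )
        corr = np.column_stack([np.arange(l_t), np.arange(l_t)])
    else:
        corr = np.asarray(correspondence, dtype=int)
        if corr.ndim != 2 or corr.shape[1] != 2 or corr.shape[0] == 0:
            raise ValueError("correspondence must be a non-empty (L, 2) array")
    mov_all = model[corr[:, 0]]
    ref_all = reference[corr[:, 1]]
    length = corr.shape[0]
    d0_sq = d0 * d0

    def score_from(sel: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            sup = kabsch_superpose(ref_all[sel], mov_all[sel])
        except ValueError:
            return -1.0, np.empty(0)
        d = np.linalg.norm(sup.apply(mov_all) - ref_all, axis=1)
        return float((1.0 / (1.0 + (d * d) / d0_sq)).sum() / l_t), d

    best = 0.0
    seeds: list[np.ndarray] = [np.arange(length)]
    for frag in (length // 2, length // 4):
        if frag < 4:
            continue
        step = max(frag // 2, 1)
        for start in range(0, length - frag + 1, step):
            seeds.append(np.arange(start, start + frag))
    start_thr = max(d0 + 1.0, 1.5)
    thresholds = list(np.arange(start_thr, 1.5 - 1e-9, -0.5))
    if not thresholds or thresholds[-1] > 1.5 + 1e-9:
        thresholds.append(1.5)
    for seed in seeds:
        for d_cut in thresholds:
            sel = seed
            seen: set[tuple[int, ...]] = set()
            while True:
                score, d = score_from(sel)
                if score > best:
                    best = score
                if d.size == 0:
                    break
                new_sel = np.flatnonzero(d <= d_cut)
                if new_sel.size < 3:
                    break
                key = tuple(new_sel.tolist())
                if key in seen:
                    break
                seen.add(key)
                sel = new_sel
    return best


def fold_consistency(
    ensembles: Sequence[Union[Ensemble, np.ndarray]],
    reference: np.ndarray,
    correspondence: Optional[np.ndarray] = None,
    threshold: float = 0.5,
) -> list[float]:
    """Per-ensemble fraction of conformations scoring TM > threshold.

    Each ensemble's models are scored against the shared reference; the
    returned fractions summarize how consistently an ensemble keeps the
    reference fold (> 0.5 meaning the same fold).
    """
    fractions = []
    for ens in ensembles:
        coords = ens.coords if isinstance(ens, Ensemble) else np.asarray(ens)
        scores = [
            tm_score(coords[m], reference, correspondence)
            for m in range(coords.shape[0])
        ]
        fractions.append(float(np.mean([s > threshold for s in scores])))
    return fractions
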