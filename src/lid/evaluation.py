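"""Pose-prediction and virtual-screening evaluation.

Pose prediction: heavy-atom ligand RMSD (optionally minimized over graph
automorphisms so symmetric ligands are not penalized), and the top-1 success
rate — the fraction of complexes whose best-ranked pose lies below 2 A RMSD
from the crystallographic ligand.  Docking is assumed rigid-receptor, so
poses share the crystal frame and no refit is applied before the RMSD.

Virtual screening: ROC AUC over active/decoy score rankings, enrichment
factors EF(x) = (actives in the top x fraction / total actives) / x, and the
true-positive percentage at a fixed decoy retrieval rate.

The reference-count titration rebuilds maps from subsets of n references
(n = 1..20, at most 1000 subsets per n) and tracks the median top-1 RMSD as
n grows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .interactions import IPA
from .maps import build_maps
from .scoring import rank_poses, score_pose
from .structures import AtomRecord


@dataclass
class PoseEvaluation:
    pose_id: str
    rmsd_to_crystal: float
    is_correct: bool

    @classmethod
    def from_rmsd(cls, pose_id: str, rmsd: float,
                  threshold: float = 2.0) -> "PoseEvaluation":
        return cls(pose_id, float(rmsd), bool(rmsd < threshold))


@dataclass
class ScreenResult:
    labels: np.ndarray
    scores: np.ndarray
    auc: float
    ef_at: dict[float, float]
    tp_at_decoy_rate: dict[float, float]


# ---------------------------------------------------------------------------
# ligand RMSD
# ---------------------------------------------------------------------------

_MAX_AUTOMORPHISMS = 10000


def _heavy(atoms: Sequence[AtomRecord]) -> list[int]:
    return [i for i, a in enumerate(atoms) if not a.is_hydrogen]


def ligand_rmsd(pose_atoms: Sequence[AtomRecord],
                crystal_atoms: Sequence[AtomRecord],
                bonds: Sequence[tuple[int, int, str]] | None = None,
                symmetry: bool = True) -> float:
    """Heavy-atom RMSD between a docked pose and the crystal ligand.

    Both atom lists must describe the same molecule in the same order and sit
    in the same frame (no refit).  With ``symmetry=True`` and a bond list,
    the RMSD is minimized over element-preserving graph automorphisms, so a
    benzene rotated by 60 degrees in place scores 0.
    """
    ph, ch = _heavy(pose_atoms), _heavy(crystal_atoms)
    if len(ph) != len(ch):
        raise ValueError(
            f"heavy-atom count mismatch: {len(ph)} vs {len(ch)}")
    p_el = [pose_atoms[i].element.upper() for i in ph]
    c_el = [crystal_atoms[i].element.upper() for i in ch]
    if sorted(p_el) != sorted(c_el):
        raise ValueError("heavy-atom element multisets differ")
    p = np.array([pose_atoms[i].coords for i in ph])
    c = np.array([crystal_atoms[i].coords for i in ch])

    def plain(perm: Sequence[int]) -> float:
        return float(np.sqrt(np.mean(np.sum((p - c[list(perm)]) ** 2, axis=1))))

    if not symmetry or bonds is None:
        if p_el != c_el:
            raise ValueError("atom order differs; symmetry matching needs bonds")
        return plain(range(len(ch)))

    # graph automorphisms of the crystal ligand, element-labelled
    remap = {orig: k for k, orig in enumerate(ch)}
    g = nx.Graph()
    for k, el in enumerate(c_el):
        g.add_node(k, element=el)
    for i, j, _ in bonds:
        if i in remap and j in remap:
            g.add_edge(remap[i], remap[j])
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    best = np.inf
    for n_seen, iso in enumerate(matcher.isomorphisms_iter()):
        perm = [iso[k] for k in range(len(c_el))]
        best = min(best, plain(perm))
        if n_seen + 1 >= _MAX_AUTOMORPHISMS:
            warnings.warn("automorphism cap reached; RMSD may be an upper bound",
                          stacklevel=2)
            break
    if not np.isfinite(best):
        raise ValueError("no element-preserving atom mapping found")
    return best


def top1_success_rate(ranked_evaluations: Sequence[Sequence[PoseEvaluation]],
                      threshold: float = 2.0) -> float:
    """Fraction of complexes whose rank-1 pose has RMSD strictly below
    *threshold* (each inner sequence is one complex, already ranked)."""
    if not ranked_evaluations:
        raise ValueError("no complexes to evaluate")
    hits = 0
    for evals in ranked_evaluations:
        if not evals:
            raise ValueError("complex with no ranked pose")
        if evals[0].rmsd_to_crystal < threshold:
            hits += 1
    return hits / len(ranked_evaluations)


# ---------------------------------------------------------------------------
# screening metrics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("need at least one active and one decoy")


def roc_auc(labels: Sequence[int], scores: Sequence[float]
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal ROC AUC (midrank tie handling) plus curve points.

    Returns ``(auc, fpr, tpr)``; labels are 1 for actives, 0 for decoys.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return float(_sk_auc(fpr, tpr)), fpr, tpr


def tp_at_decoy_rate(labels: Sequence[int], scores: Sequence[float],
                     decoy_rate: float = 0.05) -> float:
    """Percentage of actives retrieved at the score threshold where
    *decoy_rate* of the decoys are retrieved (linear interpolation between
    the bracketing whole-decoy counts)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValueError("decoy_rate must be in [0, 1]")
    active = np.sort(scores[labels])[::-1]
    decoy = np.sort(scores[~labels])[::-1]

    def tp_at_k(k: int) -> float:
        if k == 0:
            return 100.0 * float(np.mean(active > decoy[0]))
        return 100.0 * float(np.mean(active >= decoy[k - 1]))

    k = decoy_rate * len(decoy)
    k0, k1 = int(np.floor(k)), int(np.ceil(k))
    k1 = min(k1, len(decoy))
    if k0 == k1:
        return tp_at_k(k0)
    frac = k - k0
    return (1 - frac) * tp_at_k(k0) + frac * tp_at_k(k1)


def enrichment_factor(labels: Sequence[int], scores: Sequence[float],
                      fraction: float = 0.05) -> float:
    """EF(x): actives found in the top x fraction relative to random picking."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_top = max(1, int(np.ceil(fraction * len(labels))))
    order = np.argsort(-scores, kind="stable")
    top_actives = int(labels[order[:n_top]].sum())
    return (top_actives / labels.sum()) / fraction


def screen_metrics(labels: Sequence[int], scores: Sequence[float],
                   ef_fractions: Sequence[float] = (0.01, 0.05),
                   decoy_rates: Sequence[float] = (0.05,)) -> ScreenResult:
    labels_arr = np.asarray(labels, dtype=bool)
    scores_arr = np.asarray(scores, dtype=float)
    auc_val, _, _ = roc_auc(labels_arr, scores_arr)
    return ScreenResult(
        labels=labels_arr, scores=scores_arr, auc=auc_val,
        ef_at={f: enrichment_factor(labels_arr, scores_arr, f)
               for f in ef_fractions},
        tp_at_decoy_rate={r: tp_at_decoy_rate(labels_arr, scores_arr, r)
                          for r in decoy_rates},
    )


# ---------------------------------------------------------------------------
# reference-count titration
# ---------------------------------------------------------------------------

@dataclass
class TitrationComplex:
    """Poses of one ligand/complex, pre-expressed in the representative frame."""

    pose_ipas: list[list[IPA]]
    pose_rmsds: list[float]
    docking_scores: list[float] | None = None


def _sample_subsets(ids: list[str], n: int, cap: int,
                    rng: np.random.Generator) -> list[tuple[str, ...]]:
    total = comb(len(ids), n)
    if total <= cap:
        return list(itertools.combinations(ids, n))
    seen: set[tuple[str, ...]] = set()
    while len(seen) < cap:
        pick = rng.choice(len(ids), size=n, replace=False)
        seen.add(tuple(ids[i] for i in sorted(pick)))
    return sorted(seen)


def reference_titration(
    reference_ipas: Mapping[str, list[IPA]],
    complexes: Sequence[TitrationComplex],
    n_range: Sequence[int] = tuple(range(1, 21)),
    max_combinations: int = 1000,
    seed: int = 0,
    edge: float = 0.1,
    neighborhood: float = 0.5,
) -> dict[int, np.ndarray]:
    """Median top-1 RMSD as a function of the number of fused references.

    For each n, up to *max_combinations* distinct reference subsets are drawn
    (all of them when fewer exist), maps are rebuilt from each subset, every
    complex's poses are rescored and ranked, and the median over complexes of
    the rank-1 pose RMSD is recorded.  Returns ``{n: array of medians}``,
    deterministic for a given seed.
    """
    if not reference_ipas:
        raise ValueError("need at least one reference")
    ids = sorted(reference_ipas)
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for n in n_range:
        if n > len(ids):
            warnings.warn(f"titration range truncated at n={len(ids)} "
                          f"(only {len(ids)} references)", stacklevel=2)
            break
        medians = []
        for subset in _sample_subsets(ids, n, max_combinations, rng):
            ipas = [ipa for rid in subset for ipa in reference_ipas[rid]]
            mapset = build_maps(ipas, edge=edge, neighborhood=neighborhood,
                                n_references=n, provenance=list(subset))
            top1 = []
            for cx in complexes:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores = [score_pose(p, mapset, pose_id=str(k))
                              for k, p in enumerate(cx.pose_ipas)]
                ranked = rank_poses(scores, cx.docking_scores)
                best = int(ranked[0].pose_id)
                top1.append(cx.pose_rmsds[best])
            medians.append(float(np.median(top1)))
        out[n] = np.array(medians)
    return out
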