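"""The LID score: normalized density sum of a pose's IPAs against the maps.

For a pose with IPAs indexed by i (position tag M_i, interaction type T_i at
position x_i), the score is

    LID = sum_i  G(x_i, M_i, T_i) / N(M_i, T_i)

where G is the channel density map and N(M, T) the number of pose IPAs in
that channel — i.e. the sum over the 21 channels of the pose's mean map
density in that channel.  All contributions are positive; interaction types
are not weighted.

:class:`LIDScorer` packages this as a scikit-learn style density estimator:
``fit`` fuses the reference IPAs into maps, ``score_samples`` evaluates
poses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .interactions import (IPA, Channel, InteractionRecord, RuleSet,
                           all_channels, channel_code, detect_interactions,
                           to_ipa_list)
from .maps import LIDMapSet, build_maps
from .structures import StructureModel, read_ligand_records

logger = logging.getLogger(__name__)


@dataclass
class PoseScore:
    pose_id: str
    n_ipa_total: int
    n_per_channel: dict[Channel, int]
    channel_sums: dict[Channel, int]
    lid_score: float
    rank: int | None = None

    def channel_means(self) -> dict[Channel, float]:
        return {ch: (self.channel_sums.get(ch, 0) / n if n else 0.0)
                for ch, n in self.n_per_channel.items()}


def score_pose(pose_ipas: Sequence[IPA], mapset: LIDMapSet,
               pose_id: str = "pose") -> PoseScore:
    """Evaluate the normalized density sum for one pose.

    Pose IPAs must be expressed in the representative frame (the frame the
    maps were built in).  Channels present in the pose but empty in the maps
    contribute 0; an empty pose scores 0 with a warning.
    """
    if not pose_ipas:
        warnings.warn(f"pose {pose_id!r} has no IPAs; LID score is 0",
                      stacklevel=2)
        return PoseScore(pose_id, 0, {}, {}, 0.0)
    n_per: dict[Channel, int] = {}
    sums: dict[Channel, int] = {}
    for ipa in pose_ipas:
        ch = ipa.channel
        n_per[ch] = n_per.get(ch, 0) + 1
        sums[ch] = sums.get(ch, 0) + mapset.density_at(ipa.coords, ch)
    score = sum(sums[ch] / n_per[ch] for ch in n_per if n_per[ch] > 0)
    return PoseScore(pose_id, len(pose_ipas), n_per, sums, float(score))


def score_pose_file(pose_path: str | Path, protein: StructureModel,
                    mapset: LIDMapSet,
                    rules: RuleSet | None = None) -> list[PoseScore]:
    """Detect and score every ligand record of a Mol2/SDF pose file.

    Poses are assumed to already sit in the representative protein frame
    (standard rigid-receptor docking output).  Unreadable records are skipped
    with a warning; output preserves file order and pose ids.
    """
    rules = rules or RuleSet()
    out: list[PoseScore] = []
    for pose_id, atoms, bonds in read_ligand_records(pose_path):
        try:
            model = StructureModel(id=pose_id,
                                   protein_atoms=protein.protein_atoms,
                                   ligand_atoms=list(atoms),
                                   ligand_bonds=list(bonds),
                                   metals=protein.metals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records = detect_interactions(model, rules)
                out.append(score_pose(to_ipa_list(records), mapset, pose_id))
        except Exception as exc:  # noqa: BLE001 - keep screening runs alive
            logger.warning("skipping pose %r: %s", pose_id, exc)
    return out


def rank_poses(scores: Sequence[PoseScore],
               tiebreak_scores: Sequence[float] | None = None) -> list[PoseScore]:
    """Sort by descending LID score, assigning dense ranks 1..n.

    Ties are broken by descending docking score when provided (the poses
    arrive pre-scored by the docking program), else by input order.
    """
    if tiebreak_scores is not None and len(tiebreak_scores) != len(scores):
        raise ValueError("tiebreak list length does not match scores")
    idx = list(range(len(scores)))
    if tiebreak_scores is None:
        idx.sort(key=lambda i: (-scores[i].lid_score, i))
    else:
        idx.sort(key=lambda i: (-scores[i].lid_score, -tiebreak_scores[i], i))
    ranked = []
    for rank, i in enumerate(idx, start=1):
        s = scores[i]
        ranked.append(PoseScore(s.pose_id, s.n_ipa_total, s.n_per_channel,
                                s.channel_sums, s.lid_score, rank))
    return ranked


def write_scores_tsv(scores: Sequence[PoseScore], path: str | Path) -> None:
    cols = ["pose_id", "n_ipa", "lid_score", "rank"]
    chans = all_channels()
    cols += [f"mean_{channel_code(ch)}" for ch in chans]
    rows = ["\t".join(cols)]
    for s in scores:
        means = s.channel_means()
        row = [s.pose_id, str(s.n_ipa_total), f"{s.lid_score:.4f}",
               str(s.rank if s.rank is not None else "")]
        row += [f"{means.get(ch, 0.0):.4f}" for ch in chans]
        rows.append("\t".join(row))
    Path(path).write_text("\n".join(rows) + "\n")


class LIDScorer(BaseEstimator):
    """Scikit-learn style interface to LID map building and pose scoring.

    Parameters
    ----------
    edge : float, default 0.1
        Voxel edge length in Angstrom.
    neighborhood : float, default 0.5
        Manhattan neighborhood radius in Angstrom used when reading out
        densities.

    Attributes
    ----------
    maps_ : LIDMapSet
        Fused channel density maps, available after :meth:`fit`.
    n_reference_ipas_ : int
        Number of reference IPAs the maps were built from.
    """

    def __init__(self, edge: float = 0.1, neighborhood: float = 0.5):
        self.edge = edge
        self.neighborhood = neighborhood

    def fit(self, X: Sequence[IPA], y=None,
            n_references: int = 1,
            provenance: Sequence[str] = ()) -> "LIDScorer":
        """Fuse reference IPAs (representative frame) into density maps."""
        X = list(X)
        if not X:
            raise ValueError("LIDScorer.fit requires at least one reference IPA")
        self.maps_ = build_maps(X, edge=self.edge,
                                neighborhood=self.neighborhood,
                                n_references=n_references,
                                provenance=provenance)
        self.n_reference_ipas_ = len(X)
        return self

    @classmethod
    def from_maps(cls, mapset: LIDMapSet) -> "LIDScorer":
        est = cls(edge=mapset.spec.edge, neighborhood=mapset.neighborhood)
        est.maps_ = mapset
        est.n_reference_ipas_ = sum(cm.total for cm in mapset.channels.values())
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "maps_"):
            raise AttributeError("LIDScorer is not fitted; call fit() first")

    def score_samples(self, X: Iterable[Sequence[IPA]]) -> np.ndarray:
        """LID score for each pose (each element is one pose's IPA list)."""
        self._check_fitted()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array([score_pose(pose, self.maps_).lid_score
                             for pose in X])

    def score_details(self, X: Iterable[Sequence[IPA]]) -> list[PoseScore]:
        self._check_fitted()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return [score_pose(pose, self.maps_, pose_id=f"pose{i + 1}")
                    for i, pose in enumerate(X)]
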