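import warnings

import numpy as np
import pytest

from lid.interactions import (IPA, InteractionType, Mode, all_channels,
                              detect_interactions, to_ipa_list)
from lid.structures import StructureModel
from lid.synthetic import (SyntheticSiteSpec, make_pose_set,
                           make_reference_ensemble, make_representative)


def detect_ipas(model, rules=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return to_ipa_list(detect_interactions(model, rules))


def pose_ipas(representative, atoms, bonds, rules=None):
    """Detect a pose's IPAs against the representative protein."""
    model = StructureModel("pose", representative.protein_atoms, list(atoms),
                           list(bonds), representative.metals)
    return detect_ipas(model, rules)


def random_ipas(rng, n, box=20.0):
    channels = all_channels()
    return [IPA(rng.uniform(0.0, box, 3), *channels[rng.integers(len(channels))])
            for _ in range(n)]


@pytest.fixture(scope="session")
def zero_jitter_study():
    """One unjittered reference with exact planted ground truth."""
    spec = SyntheticSiteSpec(ligand_jitter=0.0, n_references=3, seed=0)
    models, truths = make_reference_ensemble(spec)
    return spec, models, truths


@pytest.fixture(scope="session")
def rigid_study():
    """Rigid-scaffold ensemble with jittered ligand binding modes."""
    spec = SyntheticSiteSpec(n_references=5, ligand_jitter=0.25, seed=11)
    models, truths = make_reference_ensemble(spec)
    rep = make_representative(spec)
    ipas = [ipa for m in models for ipa in detect_ipas(m)]
    poses = make_pose_set(spec, n_near=5, n_far=5, seed=12)
    return {"spec": spec, "models": models, "rep": rep, "ipas": ipas,
            "poses": poses}
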