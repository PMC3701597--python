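"""Shared fixtures: species library, templates, and rendered scenes.

Scene rendering and detection are the slow parts of the suite, so the
twenty two-species scenes used by the end-to-end checks are rendered
and tracked once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import fincam.classifier as clf
import fincam.features as ft
import fincam.synthetic_video as sv
import fincam.vision as vz

#: test scenes put the smelt in the upper band and the shad in the lower
#: band with a wide vertical gap, so trajectories never overlap
PAIR_SPECIES = ("delta_smelt", "threadfin_shad")


@pytest.fixture(scope="session")
def species():
    return sv.default_species()


@pytest.fixture(scope="session")
def templates(species):
    """Canonical normalized silhouette templates, one per species."""
    out = []
    for name, spec in species.items():
        mask = sv.species_silhouette(spec, 0.0, 1.5)
        out.append(ft.make_template(name, mask.astype(float), mask))
    return out


@pytest.fixture(scope="session")
def template_order(templates):
    return [t.species for t in templates]


def make_pair_scene(species, seed: int, turbidity_ntu: float,
                    smelt_row: float, shad_row: float) -> sv.SceneSpec:
    """Two fish crossing left to right on vertically separated lanes."""
    entries = (
        sv.FishEntry(spec=species["delta_smelt"], entry_frame=0,
                     entry_point=(smelt_row, -30.0), velocity=(0.0, 7.0)),
        sv.FishEntry(spec=species["threadfin_shad"], entry_frame=6,
                     entry_point=(shad_row, -30.0), velocity=(0.0, 7.0)),
    )
    return sv.SceneSpec(duration_s=1.2, fish=entries,
                        turbidity_ntu=turbidity_ntu, seed=seed)


def pair_scene_layout(i: int) -> tuple[float, float, float]:
    """(turbidity, smelt_row, shad_row) for the i-th standard scene."""
    ntu = (10.0, 20.0, 30.0)[i % 3]
    return ntu, 50.0 + (i * 13) % 90, 200.0 + (i * 7) % 60


@pytest.fixture(scope="session")
def pair_scene_results(species):
    """Twenty seeded scenes run through detection + tracking.

    Returns a list of (tracks, truth, layout) triples.
    """
    results = []
    for i in range(20):
        ntu, smelt_row, shad_row = pair_scene_layout(i)
        scene = make_pair_scene(species, 100 + i, ntu, smelt_row, shad_row)
        frames, truth = sv.render_scene(scene)
        tracks = vz.link_tracks(vz.detect_sequence(frames))
        results.append((tracks, truth, (ntu, smelt_row, shad_row)))
    return results


@pytest.fixture(scope="session")
def trained_pair_model(species, templates):
    """SVM trained on 100 rendered silhouettes per species (two classes)."""
    specs = {k: species[k] for k in PAIR_SPECIES}
    library = clf.build_silhouette_library(specs, templates,
                                           n_per_species=100, seed=0)
    return clf.train(library, clf.TrainParams(seed=0))


def truth_species_by_row(truth) -> dict:
    """Map mean ground-truth row -> species for matching tracks to truth."""
    return {
        float(np.mean([c[0] for c in t.centroids])): t.species
        for t in truth.tracks
    }
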