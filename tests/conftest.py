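"""Shared fixtures: study-condition ensembles and stand-in particles.

DFT-stage fixtures use desk-scale stand-in filaments (105 nm contour,
stiffness l_p = 25 l_c, six-helix cross section) so that the Monte Carlo
stages resolve the sign-level physics within the suite's runtime; the
geometric stages (spectra, twist/writhe) also run at the full 420 nm /
l_p = 8 l_c conditions where they are cheap.
"""

import numpy as np
import pytest

from chiralfil import interactions as itx
from chiralfil import synth

# scaled-down left-handed design used across the DFT tests:
# 2 left-handed axial turns, overwound duplexes (+6 turns/um design
# overtwist), solenoidal bias of the same handedness as the overtwist
LH_TEST = dict(
    contour_length=105.0,
    persistence_ratio=25.0,
    axial_twist_turns=-2.0,
    design_overtwist=6.0,
    writhe_coupling=0.25,
    solenoid_amplitude=3.0,
)


def make_lh_ensemble(n=30, seed=42, overtwist=None):
    lc = LH_TEST["contour_length"]
    ot = LH_TEST["design_overtwist"] if overtwist is None else overtwist
    params = synth.ChainParameters(
        contour_length=lc, segment_length=0.34,
        persistence_length=LH_TEST["persistence_ratio"] * lc,
        axial_twist_rate=LH_TEST["axial_twist_turns"] / lc * 1e3)
    geom = synth.BundleGeometry(bp_count=int(round(lc / 0.34)))
    link = synth.LinkingTarget(
        design_overtwist=ot, partition_rule="thermal",
        writhe_coupling=LH_TEST["writhe_coupling"],
        solenoid_amplitude=LH_TEST["solenoid_amplitude"])
    return synth.generate_ensemble(params, geom, link, n=n, seed=seed,
                                   design_label="1x-lh-desk")


@pytest.fixture(scope="session")
def lh_ensemble():
    """Thermalized scaled-down left-handed (overwound) design."""
    return make_lh_ensemble()


@pytest.fixture(scope="session")
def hard_model():
    """Pure steric interaction model (site charge zero)."""
    return itx.InteractionModel(site_charge=0.0)


@pytest.fixture(scope="session")
def lh_bodies(lh_ensemble, hard_model):
    """Duplex-level bead bodies of the thermalized lh ensemble."""
    return itx.coarse_grain_ensemble(lh_ensemble, hard_model,
                                     mode="duplex", target_spacing=2.0,
                                     bead_diameter=2.2)


@pytest.fixture(scope="session")
def sc_bodies():
    """Hard spherocylinder stand-in, L/D = 5."""
    return itx.BodyEnsemble.from_bodies(
        [itx.make_spherocylinder(10.0, 2.0)])


@pytest.fixture(scope="session")
def solenoid_body():
    """Rigid right-handed solenoid bead filament (strong shape chirality).
    """
    pts, axis = synth.make_solenoid_curve(84.0, 1.5, 12.0, 29)
    body_frame = np.column_stack([axis, [1.0, 0, 0], [0, 1.0, 0]])
    sites = (pts - pts.mean(axis=0)) @ body_frame
    return itx.BodyEnsemble.from_bodies(
        [itx.RigidBody(sites, np.zeros(len(sites)), 6.0, kind=0)])
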