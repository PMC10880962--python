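"""Package-wide constants and default study conditions.

Internal unit system: micrometre / nanonewton / second.  Stress is then
nN·μm⁻² = kPa, so published cartilage moduli and muscle forces are usable
verbatim.  All angles are degrees unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

# ----------------------------------------------------------------------
# time
# ----------------------------------------------------------------------
#: one developmental tracking window (12 h) in seconds
WINDOW_SECONDS = 43_200.0
#: the full 4 -> 5 dpf study period
STUDY_SECONDS = 2 * WINDOW_SECONDS

# ----------------------------------------------------------------------
# organ-level percent changes of Meckel's cartilage over 4 -> 5 dpf,
# measured from average shapes of free-to-move and immobilised larvae.
# The synthetic ground-truth deformation fields are calibrated so that
# integrating them over 24 h reproduces these numbers.
# ----------------------------------------------------------------------
ORGAN_PERCENT_CHANGES = {
    "free": {"length": 37.0, "depth": 43.0, "width": 11.0},
    "immobilised": {"length": 15.0, "depth": -6.0, "width": 4.0},
}

# ----------------------------------------------------------------------
# material properties (kPa) from nanoindentation of larval jaw cartilage
# ----------------------------------------------------------------------
CARTILAGE_E_KPA = {
    "free": {"4-4.5": 142.01, "4.5-5": 142.01, "5-5.5": 142.01},
    "immobilised": {"4-4.5": 82.91, "4.5-5": 117.44, "5-5.5": 151.96},
}
POISSON_RATIO = 0.3
#: interzone Young's modulus as a fraction of the cartilaginous modulus
INTERZONE_FRACTION = 0.025 / 100.0

# ----------------------------------------------------------------------
# muscle forces (nN) enabling physiological jaw movement; the adductor
# mandibularis (am) closes the jaw, the intermandibularis anterior (ima),
# intermandibularis posterior (imp) and interhyal (ih) open it.
# ----------------------------------------------------------------------
MUSCLE_FORCES_NN = {
    "4": {"am": 2.84, "ima": 1.25, "imp": 1.50, "ih": 1.50},
    "4.5": {"am": 4.35, "ima": 2.90, "imp": 3.47, "ih": 3.47},
}
#: physiological jaw opening (μm): ventrodorsal excursion of the MC
#: anterior tip at peak opening, for 5 dpf larvae
PHYSIOLOGICAL_OPENING_UM = 37.2

# ----------------------------------------------------------------------
# growth quantification defaults
# ----------------------------------------------------------------------
#: cubic region-of-interest side (μm)
ROI_SIZE_UM = 15.0
#: neighbour-link cutoff as a multiple of the median nearest-neighbour
#: distance (the Delaunay neighbour rule)
LINK_CUTOFF_FACTOR = 2.5
#: minimum conserved links for a valid ROI tensor
MIN_LINKS_PER_ROI = 4
#: maximum condition number of the texture matrix before an ROI is flagged
TEXTURE_CONDITION_LIMIT = 1e6

# ----------------------------------------------------------------------
# synthetic data defaults
# ----------------------------------------------------------------------
#: number of tracked chondrocytes in the modelled MC portion
N_TRACKED_CELLS = 30
#: centroid localisation noise (μm); a configuration choice representing
#: confocal segmentation uncertainty, roughly half a voxel
CENTROID_NOISE_SD_UM = 0.3
#: minimum centroid spacing for Poisson-disk sampling (μm)
MIN_CELL_SPACING_UM = 9.0
#: sub-steps per 12 h window when integrating ground-truth flows
FLOW_SUBSTEPS_PER_WINDOW = 100

# ----------------------------------------------------------------------
# morphometry defaults
# ----------------------------------------------------------------------
#: half-thickness of the joint-level slab for the width measurement (μm)
JOINT_SLAB_UM = 5.0

#: anteroposterior crop distance (μm) applied to the MC before shape
#: comparisons, restricting them to the joint region as in the outline
#: comparison protocol
MC_COMPARISON_CROP_UM = 40.0

# ----------------------------------------------------------------------
# mechanics / morphogenesis defaults
# ----------------------------------------------------------------------
#: quasi-static increments per loading step (closure, opening)
N_INCREMENTS_PER_STEP = 5
#: morphogenesis sub-steps per 12 h window
GROWTH_SUBSTEPS = 10


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalise a seed (or pass through an existing generator)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
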