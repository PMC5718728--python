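"""The known-ground-truth recovery experiment, desk scale.

A planning image is simulated (thorax-like phantom), corrupted into a
synthetic CBCT (linear gray transform + Gaussian + salt-and-pepper noise),
and deformed by a known in-plane spline field with a 10 mm maximum shift.
The edge-preserving multiscale registration (EFFD) and the plain FFD
baseline (NFFD) then recover the field; accuracy is the deformation
difference DD (mean Euclidean error, mm) against the known field.

Problem sizes are scaled down to a 64 x 64 x 8 volume at 1 x 1 x 3 mm so
the whole protocol runs in minutes on one CPU; the lambda schedule
(2.5, 0.5, 0.25) on normalized intensities was chosen from the measured
TV-L1 survival scales of the phantom's structures (finest level: noise
removed, all anatomy kept; middle: organs; coarsest: body outline only).
EFFD registers cartoons at every level, which is what makes it robust to
the CBCT noise; the baseline sees the raw images.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .registration import MultiscaleConfig, nffd_baseline, \
    register_multiscale
from .synthetic import deformation_difference, make_phantom, \
    make_registration_case, thorax_phantom_spec

__all__ = ["default_recovery_config", "recovery_case", "recovery_experiment"]

RECOVERY_SHAPE = (64, 64, 8)
RECOVERY_SPACING = (1.0, 1.0, 3.0)
# lambdas in the edge-protection regime: every level keeps all anatomy and
# progressively removes noise/fine texture (the optimal lambda in practice
# protects edges across scales rather than isolating single organs)
RECOVERY_LAMBDAS = (4.0, 3.0, 2.5)
# the known field varies on the field-of-view scale, mirroring a ~10 mm
# max shift that is smooth across a clinical volume
TRUTH_GRID_SPACING_MM = 64.0


def default_recovery_config() -> MultiscaleConfig:
    return MultiscaleConfig(
        levels=3,
        lambdas_fixed=RECOVERY_LAMBDAS,
        lambdas_moving=RECOVERY_LAMBDAS,
        subsample_factors=((1, 1, 1), (2, 2, 1), (2, 2, 1)),
        coarsest_grid_spacing=(32.0, 32.0, 84.0),
        max_iterations=25,
        min_grid_spacing_voxels=16.0,
        use_original_at_finest=True,
    )


def recovery_case(seed: int, preset: str = "D3"):
    """(fixed, moving, truth) for one noise seed of the protocol."""
    pct = make_phantom(thorax_phantom_spec(shape=RECOVERY_SHAPE,
                                           spacing=RECOVERY_SPACING,
                                           seed=0))
    return make_registration_case(pct, preset, seed=seed,
                                  grid_spacing_mm=TRUTH_GRID_SPACING_MM)


def recovery_experiment(seed: int, preset: str = "D3",
                        run_baseline: bool = True,
                        cfg: MultiscaleConfig | None = None) -> dict:
    """Run EFFD (and optionally the NFFD baseline) on one seed.

    Returns a dict with the DD of each method in mm plus the final NMI
    trace values.
    """
    cfg = cfg or default_recovery_config()
    fixed, moving, truth = recovery_case(seed, preset)
    out = {"seed": int(seed), "preset": preset,
           "mean_truth_mm": float(truth.magnitude().mean()),
           "max_truth_mm": float(truth.magnitude().max())}
    res = register_multiscale(fixed, moving, cfg)
    out["dd_effd_mm"] = deformation_difference(res.field, truth)
    out["nmi_effd"] = res.final_nmi
    if run_baseline:
        resn = nffd_baseline(fixed, moving, cfg)
        out["dd_nffd_mm"] = deformation_difference(resn.field, truth)
        out["nmi_nffd"] = resn.final_nmi
    return out
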