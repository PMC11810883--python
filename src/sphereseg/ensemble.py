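"""The spherical-projection ensemble workflow.

For each of the k projection centers: forward-project the planar input onto
the sphere, run the predictor on the projected image, and backward-project
its probability map onto the planar grid.  The k co-registered maps form a
:class:`~sphereseg.images.ProbabilityStack`; their disagreement carries the
aleatoric uncertainty signal, their mean (Otsu-thresholded, see
:mod:`sphereseg.uq`) the final segmentation.
"""

from __future__ import annotations

import numpy as np

from .backbone import PredictorContract
from .geometry import (
    ProjectionCenterSet,
    ProjectionGeometry,
    backward_project,
    forward_project,
)
from .images import PlanarImage, ProbabilityStack, SphericalImage

__all__ = ["run_spunet", "stack_mean"]

# re-exported aggregation helper lives with the uncertainty code
from .uq import stack_mean  # noqa: E402,F401


def run_spunet(
    image: PlanarImage,
    predictor: PredictorContract,
    geometry: ProjectionGeometry,
    centers: ProjectionCenterSet,
    source_image_id: str = "",
) -> ProbabilityStack:
    """Run the projection ensemble and return the k-map probability stack.

    The predictor must accept images of ``geometry.spherical_grid_size``;
    the stack is ordered as ``centers`` and deterministic given the
    predictor's seed.  Per-center predictions are independent, so results
    are identical to sequential execution regardless of scheduling.
    """
    if getattr(predictor, "input_size", None) not in (None, 0, geometry.spherical_grid_size):
        raise ValueError(
            f"predictor input size {predictor.input_size} does not match "
            f"spherical_grid_size {geometry.spherical_grid_size}"
        )
    n = geometry.planar_grid_size
    if image.pixels.shape[0] != n or image.pixels.shape[1] != n:
        raise ValueError(
            f"image shape {image.pixels.shape[:2]} does not match planar_grid_size {n}"
        )
    maps = []
    for center in centers:
        sph = forward_project(image, geometry, center)
        prob = predictor.predict(sph)
        prob_sph = SphericalImage(pixels=prob, center=center, geometry=geometry)
        planar = backward_project(prob_sph, order=1)
        maps.append(np.clip(planar.pixels, 0.0, 1.0))
    return ProbabilityStack(
        maps=np.stack(maps), centers=centers, source_image_id=source_image_id
    )
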