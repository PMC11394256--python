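"""Default normalization reference.

The color-transfer step needs reference channel statistics.  Rather than
shipping a third-party image, the package renders one well-stained
synthetic slide (fixed seed, moderate DAB coverage) and uses its
l-alpha-beta statistics as the default reference; users can point
``normalization.reference`` at their own image or at a precomputed
(mean, std) pair instead.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .io import load_rgb_image
from .normalization import ChannelStats, compute_channel_stats, rgb_to_lab_opponent
from .synthetic import FixtureParams, generate_strip_image

#: Fixed parameters of the bundled synthetic reference slide.
REFERENCE_PARAMS = FixtureParams(
    strip_angle=10.0, dab_fraction=0.25, nuclei_density=2.0, noise_sd=0.01, seed=1904
)


@lru_cache(maxsize=1)
def default_reference_stats() -> ChannelStats:
    """Channel statistics of the bundled synthetic reference slide."""
    image, _ = generate_strip_image(REFERENCE_PARAMS)
    return compute_channel_stats(rgb_to_lab_opponent(image))


def resolve_reference(reference) -> ChannelStats:
    """Turn a config ``normalization.reference`` value into ChannelStats.

    Accepts None (bundled default), a ChannelStats, a (mean, std) pair of
    3-vectors, or a path to an image file.
    """
    if reference is None:
        return default_reference_stats()
    if isinstance(reference, ChannelStats):
        return reference
    if isinstance(reference, (list, tuple)) and len(reference) == 2:
        return ChannelStats(mean=np.asarray(reference[0], float),
                            std=np.asarray(reference[1], float))
    image = load_rgb_image(reference)
    return compute_channel_stats(rgb_to_lab_opponent(image))
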