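"""Bundled worked-example data.

The ASIP series is the published ancient-DNA time series for the coat-color
locus ASIP in domesticated horses: six sampling horizons spanning roughly
20,000 years, with the derived (black-coat) allele counted among 146 sampled
haplotypes in total.  The derived allele rises sharply in frequency after
domestication and then plateaus near 0.5.  The customary analysis settings
for this locus are Ne = 16,000 and a generation time of 8 years.
"""

from __future__ import annotations

import numpy as np

from .hmm_core import TemporalObservations

__all__ = ["asip_observations", "ASIP_NE", "ASIP_GENERATION_TIME"]

ASIP_NE = 16_000.0
ASIP_GENERATION_TIME = 8.0

# (age in years BP, haplotypes sampled, derived-allele count)
_ASIP_SAMPLES = [
    (20_000, 10, 0),
    (13_100, 22, 1),
    (3_700, 20, 15),
    (2_800, 20, 12),
    (1_100, 36, 15),
    (500, 38, 18),
]


def asip_observations(
    truncate_after: int | None = None,
    generation_time: float = ASIP_GENERATION_TIME,
) -> TemporalObservations:
    """The ASIP allele-count series binned into generations.

    Generation 1 is the oldest sampling horizon; each sample's generation is
    ``floor(age / generation_time)`` counted back from the oldest horizon.
    ``truncate_after`` keeps only the first k sampled timepoints (the
    truncated-series analysis uses k = 3, the period of frequency increase).
    """
    ages = np.array([s[0] for s in _ASIP_SAMPLES], dtype=float)
    n = np.array([s[1] for s in _ASIP_SAMPLES], dtype=np.int64)
    a = np.array([s[2] for s in _ASIP_SAMPLES], dtype=np.int64)
    gen = np.floor(ages / generation_time).astype(np.int64)
    times = gen.max() - gen + 1
    obs = TemporalObservations.from_samples(int(times.max()), times, n, a)
    if truncate_after is not None:
        obs = obs.truncated(truncate_after)
    return obs
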