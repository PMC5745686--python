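"""Bundled example data.

The clinical images behind the published device comparison were never
deposited, but the per-subject coverage ratios for five subjects were, and
they make a compact worked example for the comparison utilities.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_device_cohort"]

# Published paired plaque-coverage ratios for five de-identified subjects,
# each imaged with a 405 nm fluorescence camera (pf_ratio) and a commercial
# plaque-mode intraoral camera (ref_ratio).  Deltas are never stored here;
# compute them with metrics.device_delta.
_EXAMPLE_COHORT = [
    ("M2", 0.4158, 0.1891),
    ("M3", 0.3670, 0.0213),
    ("M18", 0.2274, 0.0418),
    ("M24", 0.4869, 0.0099),
    ("M100", 0.3494, 0.0561),
]


def example_device_cohort() -> pd.DataFrame:
    """Paired per-subject ratios from both devices, as a DataFrame.

    Columns: subject_id, ref_ratio (reference device, plaque mode),
    pf_ratio (405 nm red-fluorescence device).
    """
    return pd.DataFrame(
        _EXAMPLE_COHORT, columns=["subject_id", "ref_ratio", "pf_ratio"]
    )
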