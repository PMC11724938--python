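"""Panel CSV I/O helpers and deterministic fixture generation.

The long CSV dialect is ``id,time,y1..yp,x1..xr,z1..zs[,R_*]`` with an empty
field or "NA" as the missing sentinel; lines starting with '#' (embedded
run metadata) are ignored on read.
"""

from __future__ import annotations

import numpy as np

from .missingness import apply_factor_dependent, calibrate_phi0, factor_dependent_spec
from .model import simulate_panel
from .panel import read_panel_csv, write_panel_csv
from .params import pfa_preset

__all__ = ["read_panel_csv", "write_panel_csv", "make_fixture"]

FIXTURE_SEED = 20240712


def make_fixture(seed: int = FIXTURE_SEED):
    """Small deterministic test panel: 4 persons x 12 times from the
    low-autocorrelation preset with factor-dependent masking (~30% target).

    Returns (masked panel, complete panel, true latent paths).  Regeneration
    with the same seed is bitwise-identical.
    """
    gen = pfa_preset("low")
    # calibrate on a dedicated reference panel so the tiny fixture's phi0
    # does not depend on its own 4x12 noise
    ref_panel, ref_latent = simulate_panel(gen, 100, 100, seed=seed + 1)
    spec = calibrate_phi0(ref_panel, factor_dependent_spec(), latent=ref_latent)
    panel, latent = simulate_panel(gen, 4, 12, seed=seed)
    masked = apply_factor_dependent(panel, latent, spec, seed=seed + 2)
    return masked, panel, latent
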