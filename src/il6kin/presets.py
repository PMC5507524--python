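"""Named presets for the four published exercise studies.

Each preset pairs an exercise protocol (baseline IL-6, target intensity,
duration) with the kinetic parameter set estimated when that study served as
the training dataset.  Protocols start exercising at t = 0.

=================  =====================  =========  ======  =============
preset             study                  IL6_b      T_v     duration
                                          pg·ml⁻¹    %       min
=================  =====================  =========  ======  =============
d1_ostrowski       treadmill run, 75%     1.7        67      150
d2_fischer         two-leg knee ext.      1.7        47      180
d3_steensberg      one-leg knee ext.      0.9        12      300
d4_febbraio        semi-recumbent cycle   1.8        54      120
=================  =====================  =========  ======  =============
"""

from __future__ import annotations

from .model import ExerciseProtocol, ModelParameters

__all__ = ["PROTOCOLS", "PARAMETER_SETS", "PRESET_NAMES", "get_protocol", "get_parameters"]

PROTOCOLS: dict[str, ExerciseProtocol] = {
    "d1_ostrowski": ExerciseProtocol(
        label="d1_ostrowski", t_ex_start=0.0, t_ex_end=150.0, T_v=67.0, IL6_b=1.7
    ),
    "d2_fischer": ExerciseProtocol(
        label="d2_fischer", t_ex_start=0.0, t_ex_end=180.0, T_v=47.0, IL6_b=1.7
    ),
    "d3_steensberg": ExerciseProtocol(
        label="d3_steensberg", t_ex_start=0.0, t_ex_end=300.0, T_v=12.0, IL6_b=0.9
    ),
    "d4_febbraio": ExerciseProtocol(
        label="d4_febbraio", t_ex_start=0.0, t_ex_end=120.0, T_v=54.0, IL6_b=1.8
    ),
}

# Parameter sets estimated with the named study as training data
# (SR_ex pg·ml⁻¹·min⁻¹ per %VO2max, k_m min⁻¹, k_e min⁻¹).  The
# d1_ostrowski set is the cross-validation winner and the package default
# ground truth for synthetic suites.
PARAMETER_SETS: dict[str, ModelParameters] = {
    "d1_ostrowski": ModelParameters(SR_ex=0.045, k_m=0.004, k_e=0.053),
    "d2_fischer": ModelParameters(SR_ex=0.014, k_m=0.002, k_e=0.012),
    "d3_steensberg": ModelParameters(SR_ex=0.038, k_m=0.0002, k_e=0.0047),
    "d4_febbraio": ModelParameters(SR_ex=0.637, k_m=0.00008, k_e=0.013),
}

PRESET_NAMES = tuple(PROTOCOLS)


def get_protocol(name: str) -> ExerciseProtocol:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {', '.join(PROTOCOLS)}"
        ) from None


def get_parameters(name: str) -> ModelParameters:
    try:
        return PARAMETER_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter preset {name!r}; available: {', '.join(PARAMETER_SETS)}"
        ) from None
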