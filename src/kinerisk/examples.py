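"""Published group-summary values used by the worked examples.

A motion-capture study of four youth sport skills reported, per skill,
joint ROMs (degrees) and per-muscle maximum lengthening (% of rest length,
kick side) as mean +- SD over subjects: 22 soccer players (instep kick),
9 pitchers, 7 dancers (fan kick) and 13 martial artists (axe kick). No
frame-level recordings were deposited, so these printed summaries are the
only real-data inputs available to the risk classifier and the
between-skill comparison; everything frame-level in this package runs on
synthetic motions instead.

Muscle naming note: the source tables list "semimembranosus" while the
accompanying text once names "semitendinosus" as the selected two-joint
muscle; the tables are followed here.
"""

from __future__ import annotations

from .stats import GroupSummary

__all__ = [
    "INSTEP_KICK_N",
    "FAN_KICK_N",
    "AXE_KICK_N",
    "INSTEP_KICK_MUSCLE_LENGTHENING",
    "INSTEP_KICK_ROM",
    "FAN_VS_AXE_ROM",
    "FAN_VS_AXE_MUSCLE_LENGTHENING",
    "FAN_VS_AXE_LENGTHENING_SPEED",
    "fan_axe_rom_summaries",
]

INSTEP_KICK_N = 22
FAN_KICK_N = 7
AXE_KICK_N = 13
PITCH_N = 9

#: Instep kick: max muscle lengthening, % of rest length (mean, sd).
INSTEP_KICK_MUSCLE_LENGTHENING: dict[str, tuple[float, float]] = {
    "rectus_femoris": (112.8, 8.4),
    "vastus_lateralis": (104.2, 6.1),
    "biceps_femoris": (119.3, 6.6),
    "adductor_magnus": (174.6, 11.6),
    "gracilis": (135.1, 8.6),
    "gluteus_medius": (113.2, 6.9),
    "semimembranosus": (127.7, 8.6),
}

#: Instep kick: hip and knee ROM, degrees (mean, sd).
INSTEP_KICK_ROM: dict[str, tuple[float, float]] = {
    "hip_flexion_extension": (129.0, 11.0),
    "hip_abduction_adduction": (26.0, 5.0),
    "hip_rotation": (17.0, 4.0),
    "knee_flexion_extension": (113.0, 10.0),
    "knee_abduction_adduction": (23.0, 6.0),
    "knee_rotation": (19.0, 7.0),
}

#: Fan kick vs axe kick ROM, degrees: variable -> ((fan mean, sd), (axe mean, sd)).
FAN_VS_AXE_ROM: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "hip_flexion_extension": ((146.3, 6.6), (162.2, 8.4)),
    "hip_abduction_adduction": ((87.8, 5.6), (51.6, 6.1)),
    "hip_rotation": ((54.1, 4.1), (57.9, 5.3)),
    "knee_flexion_extension": ((108.9, 6.3), (65.3, 4.7)),
    "knee_abduction_adduction": ((27.4, 4.6), (28.8, 4.1)),
    "knee_rotation": ((28.2, 4.1), (21.5, 4.3)),
}

#: Fan vs axe: max muscle lengthening, % of rest length.
FAN_VS_AXE_MUSCLE_LENGTHENING: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "rectus_femoris": ((104.2, 4.1), (105.9, 5.0)),
    "vastus_lateralis": ((109.5, 4.5), (103.6, 3.9)),
    "biceps_femoris": ((127.3, 5.2), (132.0, 4.7)),
    "adductor_magnus": ((197.7, 5.3), (171.3, 4.9)),
    "gracilis": ((134.7, 4.8), (133.8, 3.6)),
    "gluteus_medius": ((127.9, 4.0), (116.3, 3.7)),
    "semimembranosus": ((129.2, 4.4), (133.8, 4.3)),
}

#: Fan vs axe: peak lengthening speed, m/s.
FAN_VS_AXE_LENGTHENING_SPEED: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "rectus_femoris": ((0.26, 0.02), (0.48, 0.05)),
    "vastus_lateralis": ((0.09, 0.0), (0.21, 0.01)),
    "biceps_femoris": ((0.44, 0.03), (0.69, 0.05)),
    "adductor_magnus": ((0.42, 0.04), (0.61, 0.04)),
    "gracilis": ((0.13, 0.0), (0.46, 0.05)),
    "gluteus_medius": ((0.27, 0.02), (0.29, 0.02)),
    "semimembranosus": ((0.50, 0.03), (0.71, 0.06)),
}


def fan_axe_rom_summaries() -> tuple[dict[str, GroupSummary], dict[str, GroupSummary]]:
    """The fan-kick and axe-kick ROM tables as GroupSummary mappings."""
    fan = {
        var: GroupSummary(mean, sd, FAN_KICK_N)
        for var, ((mean, sd), _) in FAN_VS_AXE_ROM.items()
    }
    axe = {
        var: GroupSummary(mean, sd, AXE_KICK_N)
        for var, (_, (mean, sd)) in FAN_VS_AXE_ROM.items()
    }
    return fan, axe
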