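"""Pathological stage labels and their normalization.

Samples are ordered along tumor progression using AJCC stages I-IV; normal
adjacent tissue (NAT) serves as the control condition. Clinical tables carry
sub-stage suffixes ("Stage IIA", "Stage IIIB") which are collapsed to the
main stage; samples without a definitive I-IV stage (e.g. "Stage X") are
rejected rather than guessed.
"""

from __future__ import annotations

import re

from .exceptions import ValidationError

#: Canonical stage order used everywhere a profile is reported.
STAGE_ORDER: tuple[str, ...] = ("I", "II", "III", "IV", "NAT")

#: Tumor stages entering pattern tests (NAT is excluded from test statistics).
TUMOR_STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

_NAT_ALIASES = {
    "nat",
    "normal",
    "solid tissue normal",
    "normal adjacent tissue",
    "adjacent normal",
}

_STAGE_RE = re.compile(r"^(?:stage\s*)?(iv|iii|ii|i)[abc]?$", re.IGNORECASE)


def normalize_stage_label(raw: str) -> str:
    """Map a raw clinical stage label onto {I, II, III, IV, NAT}.

    ``"Stage IIA"``, ``"stage iia"`` and ``"IIA"`` all normalize to ``"II"``;
    NAT synonyms such as ``"Solid Tissue Normal"`` normalize to ``"NAT"``.

    Raises
    ------
    ValidationError
        If the label is empty or cannot be mapped to a definitive stage
        (e.g. ``"Stage X"``).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValidationError("empty stage label")
    text = raw.strip()
    if text.lower() in _NAT_ALIASES:
        return "NAT"
    m = _STAGE_RE.match(text)
    if m is None:
        raise ValidationError(
            f"unmappable stage label {raw!r}: expected Stage I-IV (optionally with "
            "an A/B/C sub-stage suffix) or an NAT synonym"
        )
    return m.group(1).upper()


def ordered_stages(stages) -> list[str]:
    """Return the stages present in ``stages`` in canonical I..IV, NAT order."""
    present = set(stages)
    unknown = present - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stage labels: {sorted(unknown)}")
    return [s for s in STAGE_ORDER if s in present]
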