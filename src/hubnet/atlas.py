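"""Region labels for the 90-node automated anatomical labelling parcellation.

Cortical and subcortical grey matter (cerebellum excluded) divided into 45
bilateral region pairs, interleaved left/right in the conventional atlas
order.  Connectivity matrices produced by whole-brain tractography pipelines
index their rows and columns by this order, so the label list doubles as the
canonical node ordering for every matrix in this package.
"""

from __future__ import annotations

# 45 bilateral pairs, atlas order; odd atlas indices are left hemisphere.
_BASE_LABELS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

#: The 90 region labels in atlas order (left before right within each pair).
AAL90_LABELS: list[str] = [
    f"{base}.{hemi}" for base in _BASE_LABELS for hemi in ("L", "R")
]

N_REGIONS = len(AAL90_LABELS)
assert N_REGIONS == 90

#: Index of the left middle temporal gyrus, the hub region most often
#: implicated in phonological processing.
LEFT_MTG_INDEX = AAL90_LABELS.index("MTG.L")
#: Index of the left fusiform gyrus.
LEFT_FFG_INDEX = AAL90_LABELS.index("FFG.L")


def region_index(label: str) -> int:
    """Return the atlas index of a region label (e.g. ``"MTG.L"``)."""
    try:
        return AAL90_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown region label: {label!r}") from None


def default_labels(n_regions: int) -> list[str]:
    """Labels for an ``n_regions``-node parcellation.

    The 90-node atlas gets its anatomical names; any other size gets
    positional placeholders so toy networks can flow through the same code.
    """
    if n_regions == N_REGIONS:
        return list(AAL90_LABELS)
    return [f"R{i:03d}" for i in range(n_regions)]
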