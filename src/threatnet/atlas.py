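"""Region-of-interest label fixtures and named functional networks.

The atlas layer is purely nominal: it carries the bilateral cortical and
sub-cortical region abbreviations used to label the 90-channel source space,
the six anatomically delimited baseline communities, and the three
task-related functional networks (central executive, salience, default mode)
whose node subsets feed the effective-connectivity stage.
"""

from __future__ import annotations

# Bilateral region abbreviations grouped by anatomical baseline community:
# frontal, sensorimotor, temporal, occipital, basal ganglia / sub-cortical,
# parietal.  Each base name expands to a left (.L) and right (.R) label.
BASELINE_COMMUNITIES: dict[str, list[str]] = {
    "frontal": ["FP", "SFG", "MFG", "IFGt", "IFGo", "FMC", "SC", "FO", "FOC"],
    "sensorimotor": ["PrC", "PoC", "SMA", "CO"],
    "temporal": [
        "TP", "STGa", "STGp", "MTGa", "MTGp", "MTGto",
        "ITGa", "ITGp", "ITGto", "TFCa", "TFCp", "TOF", "PP", "HG", "PT",
    ],
    "occipital": ["LOs", "LOi", "ICC", "OFG", "SP", "OP"],
    "subcortical": ["IC", "PGa", "PGp", "LV", "TH", "CA", "PU", "PA", "HI", "AM", "AC"],
    "parietal": ["SPL", "SMGa", "SMGp", "AG", "PCG", "CGa", "CGp", "PC", "CC", "LG", "POC"],
}

# Task-related functional networks emerging after stimulus onset.  Node lists
# are the bilateral members used by the effective-connectivity analyses.
FUNCTIONAL_NETWORKS: dict[str, list[str]] = {
    "CEN": ["SPL", "MFG", "CGp", "FO"],
    "SN": ["IC", "AM", "TH", "IFGo", "CGa"],
    "DMN": ["PC", "AG", "HI", "FMC", "ITGp"],
}


def _bilateral(names: list[str]) -> list[str]:
    return [f"{n}.{h}" for n in names for h in ("L", "R")]


#: Full bilateral label list in community order (112 labels).
ALL_LABELS: list[str] = [
    lab for names in BASELINE_COMMUNITIES.values() for lab in _bilateral(names)
]


def roi_labels(n: int = 90) -> list[str]:
    """Return ``n`` ROI labels.

    The first ``len(ALL_LABELS)`` labels come from the atlas fixture (the
    default source space uses the first 90); beyond that, generic
    ``ROI###`` labels are generated.
    """
    if n <= len(ALL_LABELS):
        return ALL_LABELS[:n]
    extra = [f"ROI{i:03d}" for i in range(len(ALL_LABELS), n)]
    return ALL_LABELS + extra


def network_nodes(network: str, roi_names: list[str]) -> list[int]:
    """Indices of a named functional network's members within ``roi_names``.

    Only members present in ``roi_names`` are returned; unknown network names
    raise ``KeyError``.
    """
    members = set(_bilateral(FUNCTIONAL_NETWORKS[network]))
    return [i for i, name in enumerate(roi_names) if name in members]


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def name_communities(labels, roi_names: list[str]) -> dict[int, str]:
    """Name detected communities by Jaccard overlap with the fixture lists.

    Candidates are the three functional networks and the six anatomical
    baseline communities; each detected community label maps to the candidate
    with the highest Jaccard overlap of member ROI names.
    """
    candidates: dict[str, set[str]] = {
        k: set(_bilateral(v)) for k, v in FUNCTIONAL_NETWORKS.items()
    }
    candidates.update(
        {k: set(_bilateral(v)) for k, v in BASELINE_COMMUNITIES.items()}
    )
    out: dict[int, str] = {}
    for lab in sorted(set(int(x) for x in labels)):
        members = {roi_names[i] for i, l in enumerate(labels) if int(l) == lab}
        best = max(candidates.items(), key=lambda kv: jaccard(members, kv[1]))
        out[lab] = best[0] if jaccard(members, best[1]) > 0 else "unassigned"
    return out
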