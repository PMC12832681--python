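"""The 90 cortical/subcortical region labels of the AAL atlas.

Abbreviations follow the common short form used in the connectomics
literature (e.g. ``PreCG.L`` = left precentral gyrus, ``AMYG.R`` = right
amygdala).  Regions are ordered left/right interleaved, the atlas's native
ordering, so region ``2k`` is the left and ``2k+1`` the right homologue.
"""

from __future__ import annotations

_AAL_STEMS = [
    "PreCG",      # Precentral gyrus
    "SFGdor",     # Superior frontal gyrus, dorsolateral
    "ORBsup",     # Superior frontal gyrus, orbital part
    "MFG",        # Middle frontal gyrus
    "ORBmid",     # Middle frontal gyrus, orbital part
    "IFGoperc",   # Inferior frontal gyrus, opercular part
    "IFGtriang",  # Inferior frontal gyrus, triangular part
    "ORBinf",     # Inferior frontal gyrus, orbital part
    "ROL",        # Rolandic operculum
    "SMA",        # Supplementary motor area
    "OLF",        # Olfactory cortex
    "SFGmed",     # Superior frontal gyrus, medial
    "ORBsupmed",  # Superior frontal gyrus, medial orbital
    "REC",        # Gyrus rectus
    "INS",        # Insula
    "ACG",        # Anterior cingulate gyrus
    "DCG",        # Median cingulate gyrus
    "PCG",        # Posterior cingulate gyrus
    "HIP",        # Hippocampus
    "PHG",        # Parahippocampal gyrus
    "AMYG",       # Amygdala
    "CAL",        # Calcarine fissure
    "CUN",        # Cuneus
    "LING",       # Lingual gyrus
    "SOG",        # Superior occipital gyrus
    "MOG",        # Middle occipital gyrus
    "IOG",        # Inferior occipital gyrus
    "FFG",        # Fusiform gyrus
    "PoCG",       # Postcentral gyrus
    "SPG",        # Superior parietal gyrus
    "IPL",        # Inferior parietal lobule
    "SMG",        # Supramarginal gyrus
    "ANG",        # Angular gyrus
    "PCUN",       # Precuneus
    "PCL",        # Paracentral lobule
    "CAU",        # Caudate nucleus
    "PUT",        # Putamen
    "PAL",        # Pallidum
    "THA",        # Thalamus
    "HES",        # Heschl gyrus
    "STG",        # Superior temporal gyrus
    "TPOsup",     # Temporal pole: superior temporal gyrus
    "MTG",        # Middle temporal gyrus
    "TPOmid",     # Temporal pole: middle temporal gyrus
    "ITG",        # Inferior temporal gyrus
]

#: The 90 AAL region labels, left/right interleaved.
AAL90_LABELS: list[str] = [
    f"{stem}.{side}" for stem in _AAL_STEMS for side in ("L", "R")
]

assert len(AAL90_LABELS) == 90
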