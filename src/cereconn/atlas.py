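"""Region and module vocabularies for the cerebellar connectome analysis.

The cerebellum is parcellated into 24 lobular regions (12 lobules x 2
hemispheres); the cerebrum into 400 cortical ROIs grouped into seven
cytoarchitectonic classes or seven canonical resting-state networks.
Five cerebellar modules (double-motor / triple-non-motor organisation)
are the reference partition used throughout: Primary Motor A/B, Primary
Non-Motor, Secondary Motor and Secondary Non-Motor.
"""

from __future__ import annotations

CEREBELLAR_LOBULES = [
    "I-II", "III", "IV", "V", "VI", "Crus I", "Crus II",
    "VIIb", "VIIIa", "VIIIb", "IX", "X",
]

#: 24 cerebellar region identifiers, left then right hemisphere.
CEREBELLAR_REGIONS = [f"{h}_{lob}" for h in ("L", "R") for lob in CEREBELLAR_LOBULES]

N_CEREBELLAR = 24
N_CEREBRAL = 400

#: 400 cerebral ROI identifiers (Schaefer-style numbering).
CEREBRAL_REGIONS = [f"Ctx_{i:03d}" for i in range(1, N_CEREBRAL + 1)]

#: Five cerebellar module names in canonical order.
CEREBELLAR_MODULES = ["PMA", "PMB", "PNM", "SM", "SNM"]

# Lobule -> module membership of the reference five-module solution.
# Lobule X is layer-dependent: it joins PMA in the morphological layer
# and SNM in the functional layer.
_LOBULE_MODULE_CORE = {
    "I-II": "PMA", "III": "PMA",
    "IV": "PMB", "V": "PMB", "VI": "PMB",
    "Crus I": "PNM", "Crus II": "PNM",
    "VIIb": "SM", "VIIIa": "SM", "VIIIb": "SM",
    "IX": "SNM",
}


def reference_partition(layer: str = "functional") -> dict[str, str]:
    """Region -> module labels of the reference five-module architecture.

    Parameters
    ----------
    layer:
        ``"morphological"`` places bilateral Lobule X in PMA,
        ``"functional"`` places it in SNM.
    """
    if layer not in ("morphological", "functional"):
        raise ValueError(f"unknown layer {layer!r}")
    x_module = "PMA" if layer == "morphological" else "SNM"
    out = {}
    for region in CEREBELLAR_REGIONS:
        lob = region.split("_", 1)[1]
        out[region] = _LOBULE_MODULE_CORE.get(lob, x_module)
    return out


#: Seven cytoarchitectonic cerebral classes.
CYTO_MODULES = ["PM", "AC1", "AC2", "PSS", "PS", "LB", "IC"]

#: Seven canonical resting-state functional networks.
FUNC_MODULES = ["VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN"]

TAXONOMIES = {"cytoarchitectonic": CYTO_MODULES, "functional": FUNC_MODULES}
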