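"""Distance-based reclassification of vereda pixels.

Vereda reference sites are centred on palm stands, so the waterlogged
herbaceous matrix that surrounds real veredas maps as campo limpo umido
(CLU). A mapped vereda pixel far from any CLU pixel is therefore almost
certainly a commission error. The rule: if a vereda (V) pixel lies more
than a threshold distance (default 100 m, centre-to-centre Euclidean) from
the nearest CLU pixel, replace it with the most common savanna/forest
woody physiognomy — cerrado sensu stricto, cerrado rupestre, cerradao or
mata de galeria — inside a moving window (default 1 ha, i.e. 5x5 at 20 m)
centred on the pixel. Distances and window modes are evaluated against
the ORIGINAL map (one simultaneous pass); only V pixels can change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classify import ClassifiedMap

__all__ = ["ReclassParams", "vereda_reclassify"]


@dataclass(frozen=True)
class ReclassParams:
    max_distance_m: float = 100.0
    window_area_m2: float = 10_000.0
    #: mode candidates, in fixed tie-break order (first wins ties)
    candidates: tuple[str, ...] = ("CSS", "CERR", "C", "MG")

    def __post_init__(self) -> None:
        if self.max_distance_m <= 0:
            raise ValueError("distance threshold must be > 0")
        if self.window_area_m2 <= 0:
            raise ValueError("window area must be positive")


def vereda_reclassify(cmap: ClassifiedMap,
                      params: ReclassParams = ReclassParams()
                      ) -> tuple[ClassifiedMap, dict]:
    """Apply the vereda distance rule; returns the new map and a report
    (pixels examined/reclassified, per-replacement-class counts, and the
    count left unchanged for lack of a candidate in the window)."""
    scheme = cmap.scheme
    px = cmap.grid.pixel_size
    codes = cmap.class_codes
    v_code = scheme.code_of["V"]
    clu_code = scheme.code_of["CLU"]

    v_mask = codes == v_code
    report = {"n_vereda": int(v_mask.sum()), "n_reclassified": 0,
              "n_unresolvable": 0,
              "replacements": {c: 0 for c in params.candidates}}
    if not v_mask.any():
        return cmap, report

    # centre-to-centre distance (m) to the nearest CLU pixel; infinite when
    # the map holds no CLU at all
    clu_mask = codes == clu_code
    if clu_mask.any():
        dist = ndimage.distance_transform_edt(~clu_mask) * px
    else:
        dist = np.full(codes.shape, np.inf)
    too_far = v_mask & (dist > params.max_distance_m)

    size = int(round(np.sqrt(params.window_area_m2) / px))
    if size % 2 == 0:
        size += 1
    size = max(size, 1)
    half = size // 2

    new_codes = codes.copy()
    rows, cols = codes.shape
    cand_codes = [scheme.code_of[c] for c in params.candidates]
    for r, c in np.argwhere(too_far):
        window = codes[max(r - half, 0):r + half + 1,
                       max(c - half, 0):c + half + 1]
        counts = [(window == cc).sum() for cc in cand_codes]
        best = int(np.argmax(counts))  # ties: first candidate in order
        if counts[best] == 0:
            report["n_unresolvable"] += 1
            continue
        new_codes[r, c] = cand_codes[best]
        report["n_reclassified"] += 1
        report["replacements"][params.candidates[best]] += 1

    new_stage = cmap.stage.copy()
    out = ClassifiedMap(new_codes, new_stage, cmap.probability.copy(),
                        cmap.grid, scheme,
                        {**cmap.provenance, "vereda_reclassified":
                         report["n_reclassified"]})
    return out, report
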