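"""Hierarchical land-cover class scheme for Cerrado vegetation mapping.

Two levels are distinguished:

* stage 1 — three native *formations* (grassland GRA, savanna SAV, forest
  FOR) plus five other covers (pasture PAST, plantation forest PF,
  agriculture A, water W, non-vegetated NV);
* stage 2 — eight native *physiognomies* nested inside the formations:
  campo limpo umido (CLU), campo seco (CS), campo rupestre (CAMR) in GRA;
  cerrado sensu stricto (CSS), cerrado rupestre (CERR), vereda (V) in SAV;
  cerradao (C), mata de galeria (MG) in FOR.

Codes are ASCII (CLU for "campo limpo úmido", C for "cerradão", ...).
Together the 8 physiognomies and 5 other covers form the 13 terminal
land-cover types a finished map can carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: physiognomy code -> formation code
FORMATION_OF = {
    "CLU": "GRA", "CS": "GRA", "CAMR": "GRA",
    "CSS": "SAV", "CERR": "SAV", "V": "SAV",
    "C": "FOR", "MG": "FOR",
}

OTHER_COVERS = ("PAST", "PF", "A", "W", "NV")
NATIVE_FORMATIONS = ("GRA", "SAV", "FOR")

CLASS_NAMES = {
    "CLU": "campo limpo umido", "CS": "campo seco", "CAMR": "campo rupestre",
    "CSS": "cerrado sensu stricto", "CERR": "cerrado rupestre", "V": "vereda",
    "C": "cerradao", "MG": "mata de galeria",
    "GRA": "grassland formation", "SAV": "savanna formation",
    "FOR": "forest formation",
    "PAST": "pasture", "PF": "plantation forest", "A": "agriculture",
    "W": "water", "NV": "non-vegetated",
}


@dataclass(frozen=True)
class ClassScheme:
    """The two-level label set and its code<->integer mappings.

    Integer codes are used on raster grids: terminal classes get stable
    positive codes, stage-1 formations get their own codes (used on
    formation-level maps), 0 is "unclassified" and ``nodata_code`` marks
    invalid pixels.
    """

    physiognomies: tuple[str, ...] = tuple(FORMATION_OF)
    other_covers: tuple[str, ...] = OTHER_COVERS
    formations: tuple[str, ...] = NATIVE_FORMATIONS
    nodata_code: int = -1
    unclassified_code: int = 0
    code_of: dict[str, int] = field(default_factory=dict)
    class_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.physiognomies) != 8 or len(self.formations) != 3:
            raise ValueError("scheme requires 8 physiognomies in 3 formations")
        for p in self.physiognomies:
            if p not in FORMATION_OF:
                raise ValueError(f"unknown physiognomy {p!r}")
        codes = {}
        for i, c in enumerate(
            tuple(self.physiognomies) + tuple(self.other_covers)
            + tuple(self.formations)
        ):
            codes[c] = i + 1
        object.__setattr__(self, "code_of", codes)
        object.__setattr__(self, "class_of", {v: k for k, v in codes.items()})

    # ---- level queries -------------------------------------------------
    @property
    def terminal_classes(self) -> tuple[str, ...]:
        """The 13 classes a finished physiognomy-level map can carry."""
        return tuple(self.physiognomies) + tuple(self.other_covers)

    @property
    def stage1_classes(self) -> tuple[str, ...]:
        """The 8 classes of the formation-level classification."""
        return tuple(self.formations) + tuple(self.other_covers)

    def formation(self, terminal: str) -> str:
        """Stage-1 class of a terminal class (identity for other covers)."""
        if terminal in FORMATION_OF:
            return FORMATION_OF[terminal]
        if terminal in self.other_covers:
            return terminal
        raise KeyError(f"unknown terminal class {terminal!r}")

    def physiognomies_of(self, formation: str) -> tuple[str, ...]:
        if formation not in self.formations:
            raise KeyError(f"not a native formation: {formation!r}")
        return tuple(p for p, f in FORMATION_OF.items() if f == formation)

    def is_native(self, cls: str) -> bool:
        return cls in FORMATION_OF or cls in self.formations


DEFAULT_SCHEME = ClassScheme()
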