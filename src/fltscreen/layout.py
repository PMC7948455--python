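"""Microplate layouts: well labels, roles, and the LOPAC screening map.

Wells are labelled row-letter + zero-padded column ("A01" .. "AF48" on a
1536-well plate). Rows run A..Z then AA..AF; rows and columns are 1-based
in files and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

ROLES = ("dmso", "compound", "tool", "empty")

#: plate format -> (n_rows, n_cols)
PLATE_FORMATS: Dict[int, Tuple[int, int]] = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

# LOPAC 1536-well map: compounds in columns 3-22 and 27-46, DMSO elsewhere.
LOPAC_COMPOUND_COLUMNS: Tuple[range, ...] = (range(3, 23), range(27, 47))
LOPAC_DMSO_COLUMNS: Tuple[range, ...] = (range(1, 3), range(23, 27), range(47, 49))


def row_label(row: int) -> str:
    """1-based row index -> letter label (1->'A', 26->'Z', 27->'AA')."""
    if row < 1:
        raise ValueError(f"row index must be >= 1, got {row}")
    label = ""
    n = row
    while n > 0:
        n, rem = divmod(n - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def parse_row_label(label: str) -> int:
    """Letter label -> 1-based row index ('A'->1, 'AF'->32)."""
    if not label or not label.isalpha():
        raise ValueError(f"malformed row label {label!r}")
    n = 0
    for ch in label.upper():
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n


def well_label(row: int, col: int) -> str:
    """1-based (row, col) -> well label like 'A01'."""
    return f"{row_label(row)}{col:02d}"


def parse_well_label(label: str) -> Tuple[int, int]:
    """Well label -> 1-based (row, col)."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    if i == 0 or i == len(label) or not label[i:].isdigit():
        raise ValueError(f"malformed well label {label!r}")
    return parse_row_label(label[:i]), int(label[i:])


@dataclass
class Well:
    """One well of a plate layout."""

    row: int
    col: int
    role: str
    compound_id: Optional[str] = None
    conc_uM: Optional[float] = None

    @property
    def label(self) -> str:
        return well_label(self.row, self.col)


@dataclass
class PlateLayout:
    """Maps every well of a plate to a role, compound id and concentration.

    ``role`` is one of ``dmso`` (negative control), ``compound`` (library
    member), ``tool`` (positive-control tool compound) or ``empty``.
    """

    plate_format: int
    wells: List[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(
                f"unsupported plate format {self.plate_format}; "
                f"supported formats: {sorted(PLATE_FORMATS)}"
            )
        seen = set()
        for w in self.wells:
            if w.role not in ROLES:
                raise ValueError(f"unknown role {w.role!r} for well {w.label}")
            if (w.row, w.col) in seen:
                raise ValueError(f"duplicate well {w.label}")
            seen.add((w.row, w.col))

    @property
    def shape(self) -> Tuple[int, int]:
        return PLATE_FORMATS[self.plate_format]

    def __len__(self) -> int:
        return len(self.wells)

    def wells_with_role(self, role: str) -> List[Well]:
        return [w for w in self.wells if w.role == role]

    @property
    def compound_wells(self) -> List[Well]:
        return self.wells_with_role("compound")

    @property
    def dmso_wells(self) -> List[Well]:
        return self.wells_with_role("dmso")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per well (well,row,col,role,compound_id,conc_uM)."""
        return pd.DataFrame(
            {
                "well": [w.label for w in self.wells],
                "row": [w.row for w in self.wells],
                "col": [w.col for w in self.wells],
                "role": [w.role for w in self.wells],
                "compound_id": [w.compound_id for w in self.wells],
                "conc_uM": [w.conc_uM for w in self.wells],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, plate_format: Optional[int] = None) -> "PlateLayout":
        """Build a layout from a tidy per-well table (inverse of :meth:`to_frame`)."""
        if plate_format is None:
            plate_format = _infer_format(df)
        wells = [
            Well(
                row=int(r.row),
                col=int(r.col),
                role=str(r.role),
                compound_id=None if pd.isna(r.compound_id) else str(r.compound_id),
                conc_uM=None if pd.isna(r.conc_uM) else float(r.conc_uM),
            )
            for r in df.itertuples()
        ]
        return cls(plate_format=plate_format, wells=wells)

    def compound_ids(self) -> List[str]:
        out: List[str] = []
        seen = set()
        for w in self.compound_wells:
            if w.compound_id is not None and w.compound_id not in seen:
                seen.add(w.compound_id)
                out.append(w.compound_id)
        return out


def _infer_format(df: pd.DataFrame) -> int:
    n = len(df)
    for fmt in PLATE_FORMATS:
        if n == fmt:
            return fmt
    raise ValueError(
        f"cannot infer plate format from {n} wells; "
        f"expected one of {sorted(PLATE_FORMATS)}"
    )


def make_lopac_layout(plate_format: int = 1536, concentration_uM: float = 10.0) -> PlateLayout:
    """Build the 1536-well LOPAC pilot-screen layout.

    Compounds sit in columns 3-22 and 27-46 across all 32 rows (1280 wells,
    compound ids ``C0001``..``C1280`` in row-major order over compound wells);
    DMSO negative controls fill columns 1-2, 23-26 and 47-48 (256 wells).

    Parameters
    ----------
    plate_format : int
        Only the 1536-well format carries the LOPAC map.
    concentration_uM : float
        Screening concentration assigned to every compound well (10 uM final
        for 5 nl of 10 mM stock in ~5 ul).
    """
    if plate_format != 1536:
        raise ValueError(
            f"LOPAC layout is defined for the 1536-well format only, got {plate_format}; "
            "use make_uniform_layout for other formats"
        )
    n_rows, n_cols = PLATE_FORMATS[plate_format]
    compound_cols = {c for rng in LOPAC_COMPOUND_COLUMNS for c in rng}
    wells: List[Well] = []
    k = 0
    for row in range(1, n_rows + 1):
        for col in range(1, n_cols + 1):
            if col in compound_cols:
                k += 1
                wells.append(
                    Well(row, col, "compound", compound_id=f"C{k:04d}", conc_uM=concentration_uM)
                )
            else:
                wells.append(Well(row, col, "dmso"))
    return PlateLayout(plate_format=plate_format, wells=wells)


def make_uniform_layout(
    plate_format: int,
    dmso_columns: Iterable[int] = (1, 2),
    tool_columns: Iterable[int] = (),
    concentration_uM: float = 10.0,
    compound_prefix: str = "C",
) -> PlateLayout:
    """Generic layout: chosen columns are DMSO / tool, the rest compounds.

    Useful for reduced-scale (384-well) simulations and for Z'-style plates
    (half DMSO, half tool) via ``tool_columns``.
    """
    if plate_format not in PLATE_FORMATS:
        raise ValueError(
            f"unsupported plate format {plate_format}; supported: {sorted(PLATE_FORMATS)}"
        )
    n_rows, n_cols = PLATE_FORMATS[plate_format]
    dmso = set(dmso_columns)
    tool = set(tool_columns)
    if dmso & tool:
        raise ValueError("a column cannot be both DMSO and tool")
    wells: List[Well] = []
    k = 0
    for row in range(1, n_rows + 1):
        for col in range(1, n_cols + 1):
            if col in dmso:
                wells.append(Well(row, col, "dmso"))
            elif col in tool:
                wells.append(Well(row, col, "tool", compound_id="TOOL", conc_uM=concentration_uM))
            else:
                k += 1
                wells.append(
                    Well(
                        row,
                        col,
                        "compound",
                        compound_id=f"{compound_prefix}{k:04d}",
                        conc_uM=concentration_uM,
                    )
                )
    return PlateLayout(plate_format=plate_format, wells=wells)


def make_zprime_layout(plate_format: int = 1536) -> PlateLayout:
    """Half-DMSO / half-tool plate used for Z'-factor determination.

    Columns in the left half carry the DMSO negative control and the right
    half the tool compound (768 + 768 wells at the 1536 format).
    """
    if plate_format not in PLATE_FORMATS:
        raise ValueError(
            f"unsupported plate format {plate_format}; supported: {sorted(PLATE_FORMATS)}"
        )
    _, n_cols = PLATE_FORMATS[plate_format]
    half = n_cols // 2
    return make_uniform_layout(
        plate_format,
        dmso_columns=range(1, half + 1),
        tool_columns=range(half + 1, n_cols + 1),
    )
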