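"""13C chemical shifts of labeled Abeta40 residues in frozen solutions.

Shifts (ppm, DSS-referenced) at resolved or partially resolved crosspeak
maxima for the monomeric (pH 12), oligomeric and fibrillar states, plus
random-coil reference values (Wishart-style tabulation).  The companion
linewidth is the approximate FWHM in ppm.  ``None`` marks entries that were
not recorded, unresolved, or whose linewidth was obscured by overlap.

These printed values serve as inputs: to the shift-based secondary-structure
classifier, and as realistic peak lists for synthetic 2D spectra.
"""

from __future__ import annotations

from .nmr import ShiftRecord

__all__ = ["SHIFT_TABLE", "get_record", "records_for", "beta_indicative_residues", "RESIDUES"]

RESIDUES = ["V18", "F19", "V24", "G25", "S26", "A30", "I31", "G33", "L34", "M35"]

# (residue, atom, state) -> (shift ppm, FWHM ppm or None)
# states: mono, oligo, fib, coil.  FWHM is twice the tabulated half-width.
SHIFT_TABLE: dict[tuple[str, str, str], tuple[float, float | None]] = {
    ("V18", "CO", "mono"): (175.6, 4.2),
    ("V18", "CO", "oligo"): (174.2, 4.0),
    ("V18", "CO", "coil"): (176.3, None),
    ("V18", "CA", "mono"): (62.5, 5.0),
    ("V18", "CA", "oligo"): (61.0, 3.6),
    ("V18", "CA", "coil"): (62.2, None),
    ("V18", "CB", "mono"): (34.5, 5.0),
    ("V18", "CB", "oligo"): (36.0, 4.0),
    ("V18", "CB", "coil"): (32.9, None),
    ("V18", "CG", "mono"): (22.4, 5.4),
    ("V18", "CG", "oligo"): (22.0, 5.8),
    ("F19", "CO", "fib"): (173.4, 2.4),
    ("F19", "CO", "coil"): (175.8, None),
    ("F19", "CA", "mono"): (58.5, None),
    ("F19", "CA", "oligo"): (57.0, 4.0),
    ("F19", "CA", "fib"): (56.3, 3.6),
    ("F19", "CA", "coil"): (57.5, None),
    ("F19", "CB", "mono"): (40.3, 5.6),
    ("F19", "CB", "oligo"): (42.6, 6.0),
    ("F19", "CB", "fib"): (44.3, 2.6),
    ("F19", "CB", "coil"): (39.6, None),
    ("V24", "CO", "mono"): (176.1, 5.4),
    ("V24", "CO", "fib"): (174.8, 3.0),
    ("V24", "CO", "coil"): (176.3, None),
    ("V24", "CA", "mono"): (63.3, 6.0),
    ("V24", "CA", "oligo"): (61.7, 5.0),
    ("V24", "CA", "fib"): (60.8, 2.6),
    ("V24", "CA", "coil"): (62.2, None),
    ("V24", "CB", "mono"): (32.0, None),
    ("V24", "CB", "oligo"): (33.0, 6.0),
    ("V24", "CB", "fib"): (35.7, None),
    ("V24", "CB", "coil"): (32.9, None),
    ("V24", "CG", "fib"): (21.3, None),
    ("G25", "CO", "mono"): (175.5, 5.4),
    ("G25", "CO", "oligo"): (174.7, 4.8),
    ("G25", "CO", "fib"): (173.6, 3.2),
    ("G25", "CO", "coil"): (174.9, None),
    ("G25", "CA", "mono"): (45.7, 3.8),
    ("G25", "CA", "oligo"): (45.5, 5.0),
    ("G25", "CA", "fib"): (47.0, 4.2),
    ("G25", "CA", "coil"): (45.1, None),
    ("S26", "CO", "mono"): (174.3, 3.2),
    ("S26", "CO", "oligo"): (174.3, 4.0),
    ("S26", "CO", "fib"): (174.5, 5.4),
    ("S26", "CO", "coil"): (174.6, None),
    ("S26", "CA", "mono"): (58.6, 5.4),
    ("S26", "CA", "oligo"): (58.5, 4.0),
    ("S26", "CA", "fib"): (58.0, 4.0),
    ("S26", "CA", "coil"): (58.3, None),
    ("S26", "CB", "mono"): (64.0, 4.8),
    ("S26", "CB", "oligo"): (64.0, 6.0),
    ("S26", "CB", "fib"): (66.2, 4.8),
    ("S26", "CB", "coil"): (63.8, None),
    ("A30", "CO", "mono"): (177.7, 4.4),
    ("A30", "CO", "oligo"): (175.6, 4.0),
    ("A30", "CO", "fib"): (175.3, 3.2),
    ("A30", "CO", "coil"): (177.8, None),
    ("A30", "CA", "mono"): (53.5, 3.0),
    ("A30", "CA", "oligo"): (52.1, 3.6),
    ("A30", "CA", "fib"): (52.3, 2.0),
    ("A30", "CA", "coil"): (52.5, None),
    ("A30", "CB", "mono"): (20.5, 5.0),
    ("A30", "CB", "oligo"): (22.2, 6.8),
    ("A30", "CB", "fib"): (20.2, 2.8),
    ("A30", "CB", "coil"): (19.1, None),
    ("I31", "CO", "mono"): (176.1, 5.4),
    ("I31", "CO", "oligo"): (175.6, 4.0),
    ("I31", "CO", "fib"): (174.8, 3.0),
    ("I31", "CO", "coil"): (176.4, None),
    ("I31", "CA", "mono"): (62.3, None),
    ("I31", "CA", "oligo"): (60.6, 4.6),
    ("I31", "CA", "fib"): (60.8, 2.4),
    ("I31", "CA", "coil"): (61.1, None),
    ("I31", "CB", "mono"): (39.0, 5.6),
    ("I31", "CB", "oligo"): (42.3, 5.0),
    ("I31", "CB", "fib"): (41.2, 3.0),
    ("I31", "CB", "coil"): (38.8, None),
    ("I31", "CG1", "oligo"): (28.6, 7.2),
    ("I31", "CG1", "fib"): (28.6, 3.2),
    ("I31", "CG1", "coil"): (27.2, None),
    ("I31", "CG2", "oligo"): (17.4, 6.4),
    ("I31", "CG2", "fib"): (18.8, None),
    ("I31", "CG2", "coil"): (17.4, None),
    ("G33", "CO", "mono"): (173.9, 5.2),
    ("G33", "CO", "oligo"): (170.7, 3.2),
    ("G33", "CO", "coil"): (174.9, None),
    ("G33", "CA", "mono"): (46.1, 3.6),
    ("G33", "CA", "oligo"): (44.9, 3.8),
    ("G33", "CA", "coil"): (45.1, None),
    ("L34", "CO", "mono"): (176.2, 5.0),
    ("L34", "CO", "fib"): (173.4, 3.0),
    ("L34", "CO", "coil"): (177.6, None),
    ("L34", "CA", "mono"): (56.2, 5.6),
    ("L34", "CA", "fib"): (56.2, 3.8),
    ("L34", "CA", "coil"): (55.1, None),
    ("L34", "CB", "mono"): (42.0, 6.8),
    ("L34", "CB", "oligo"): (45.5, 7.0),
    ("L34", "CB", "fib"): (41.4, 3.6),
    ("L34", "CB", "coil"): (42.4, None),
    ("L34", "CG", "mono"): (27.5, 5.8),
    ("L34", "CG", "oligo"): (28.8, 6.0),
    ("L34", "CG", "fib"): (28.6, 2.4),
    ("L34", "CG", "coil"): (26.9, None),
    ("M35", "CO", "mono"): (177.3, 4.6),
    ("M35", "CO", "oligo"): (174.7, 5.8),
    ("M35", "CO", "fib"): (173.4, 3.0),
    ("M35", "CO", "coil"): (176.3, None),
    ("M35", "CA", "mono"): (55.2, 5.6),
    ("M35", "CA", "oligo"): (54.6, 3.0),
    ("M35", "CA", "fib"): (55.0, 2.4),
    ("M35", "CA", "coil"): (55.4, None),
    ("M35", "CB", "fib"): (36.1, None),
    ("M35", "CB", "coil"): (32.9, None),
    ("M35", "CG", "fib"): (33.0, None),
    ("M35", "CG", "coil"): (32.0, None),
}


def get_record(residue: str, atom: str, state: str) -> ShiftRecord | None:
    """Shift record for one site and state, or ``None`` if unresolved or
    not recorded."""
    entry = SHIFT_TABLE.get((residue, atom, state))
    if entry is None:
        return None
    shift, fwhm = entry
    return ShiftRecord(residue=residue, atom=atom, shift=shift, fwhm=fwhm, state=state)


def records_for(state: str, residues=None) -> list[ShiftRecord]:
    """All records of one state, table order."""
    out = []
    for (res, atom, st), (shift, fwhm) in SHIFT_TABLE.items():
        if st == state and (residues is None or res in residues):
            out.append(ShiftRecord(residue=res, atom=atom, shift=shift, fwhm=fwhm, state=st))
    return out


def beta_indicative_residues(
    ref_state: str = "mono", state: str = "oligo", atoms: tuple[str, ...] = ("CO", "CA")
) -> list[str]:
    """Residues whose shift change between two states is beta-indicative
    for at least one of the given atoms (entries unresolved in either state
    are skipped)."""
    from .nmr import classify_secondary_shift

    hits = []
    for res in RESIDUES:
        for atom in atoms:
            ref = get_record(res, atom, ref_state)
            obs = get_record(res, atom, state)
            if ref is None or obs is None:
                continue
            if classify_secondary_shift(ref, obs) == "beta-indicative":
                hits.append(res)
                break
    return hits
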