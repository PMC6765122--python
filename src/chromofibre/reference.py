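"""Published reference parameters of compact crossed-linker fibre models.

One row per predicted 32-mer fibre (uniform NRL) or 16-repeat two-NRL unit
(alternating NRL).  ``linker_bp`` is the equivalent linker length N (bp,
fractional: the modelled linker is continuous even though real linkers are
integer bp); ``wr_per_nuc`` the writhe per nucleosome of the 32-mer DNA
path; ``dl_per_nuc`` the linking-number change per nucleosome obtained by
adding the linker twist change for a 10.5 -> 10 bp/turn over-twist.  These
values serve as regression anchors for the topology bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FibreReferenceRow", "COMPACT_FIBRE_TABLE"]


@dataclass(frozen=True)
class FibreReferenceRow:
    label: str  # e.g. "(-177-)32" or "(-177-187-)16"
    nrl_bp: tuple[int, ...]  # one entry (uniform) or two (alternating)
    linker_bp: float
    diameter_nm: float
    nuc_per_11nm: float
    connectivity: str
    start_mode: str
    wr_per_nuc: float
    dl_per_nuc: float

    @property
    def uniform(self) -> bool:
        return len(self.nrl_bp) == 1


COMPACT_FIBRE_TABLE: list[FibreReferenceRow] = [
    FibreReferenceRow("(-177-)32", (177,), 29.14, 28.6, 7.0, "i ± 2", "2-start", -1.580, -1.441),
    FibreReferenceRow("(-177-187-)16", (177, 187), 34.26, 30.7, 9.2, "i ± 2", "2-start", -1.594, -1.431),
    FibreReferenceRow("(-187-)32", (187,), 39.68, 32.2, 10.3, "i ± 2", "2-start", -1.616, -1.428),
    FibreReferenceRow("(-187-197-)16", (187, 197), 44.29, 34.8, 11.2, "i ± 2", "2-start", -1.611, -1.400),
    FibreReferenceRow("(-197-)32", (197,), 49.75, 35.7, 10.7, "i ± 2", "2-start", -1.608, -1.371),
    FibreReferenceRow("(-197-207-)16", (197, 207), 54.33, 38.6, 12.4, "i ± 2", "2-start", -1.619, -1.360),
    FibreReferenceRow("(-197-)32", (197,), 48.87, 37.4, 10.8, "i ± 7, i ± 9", "1-start", -1.687, -1.454),
    FibreReferenceRow("(-197-207-)16", (197, 207), 54.28, 38.4, 11.5, "i ± 7, i ± 9", "1-start", -1.705, -1.446),
    FibreReferenceRow("(-207-)32", (207,), 58.86, 39.5, 11.0, "i ± 7, i ± 9", "1-start", -1.683, -1.403),
    FibreReferenceRow("(-217-207-)16", (217, 207), 64.51, 39.7, 12.0, "i ± 7, i ± 9", "1-start", -1.706, -1.399),
    FibreReferenceRow("(-217-)32", (217,), 69.35, 42.1, 13.6, "i ± 9, i ± 11", "1-start", -1.693, -1.363),
    FibreReferenceRow("(-227-217-)16", (227, 217), 75.14, 43.3, 13.2, "i ± 7, i ± 9", "1-start", -1.767, -1.409),
    FibreReferenceRow("(-227-)32", (227,), 79.90, 45.0, 14.5, "i ± 9, i ± 11", "1-start", -1.747, -1.367),
    FibreReferenceRow("(-237-227-)16", (237, 227), 85.17, 47.1, 15.2, "i ± 9, i ± 11", "1-start", -1.765, -1.359),
    FibreReferenceRow("(-237-217-)16", (237, 217), 80.28, 45.0, 13.6, "i ± 7, i ± 9", "1-start", -1.767, -1.385),
    FibreReferenceRow("(-237-)32", (237,), 90.26, 48.1, 13.4, "i ± 9, i ± 11", "1-start", -1.779, -1.349),
]
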