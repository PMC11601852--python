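"""The located-match record shared by the oracle, the locator, and the aligner."""

from __future__ import annotations

from dataclasses import dataclass

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True, order=True)
class Occurrence:
    """One match of a query in the indexed text.

    ``start``/``length`` delimit the half-open text span ``[start, start+length)``,
    which never overlaps the sentinel. ``distance`` is the error count under
    ``metric`` ("hamming" or "edit"); ``strand`` is "+" for the query as given
    and "-" for its reverse complement.
    """

    start: int
    length: int
    distance: int
    strand: str = FORWARD
    metric: str = "hamming"
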