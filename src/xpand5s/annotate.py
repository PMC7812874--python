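"""Record annotation: numbering plus expansion-segment extraction."""

from __future__ import annotations

from .numbering import (CoreAlignmentMap, ExpansionSegment, align_to_core,
                        extract_insertions)
from .schema import CoreSchema


def annotate_record(seq: str, schema: CoreSchema, record_id: str = "record",
                    taxon: str = "", min_len: int = 10
                    ) -> tuple[CoreAlignmentMap, list[ExpansionSegment]]:
    """Number a prefiltered record against ``schema`` and return its map
    together with every expansion segment of at least ``min_len`` nt.

    Alignment failures (anchor seeds absent) propagate as
    :class:`~xpand5s.numbering.AlignmentError`.
    """
    cmap = align_to_core(seq, schema, query_id=record_id)
    segments = extract_insertions(cmap, min_len=min_len)
    if taxon:
        segments = [
            ExpansionSegment(host_id=s.host_id, site=s.site, sequence=s.sequence,
                             start=s.start, taxon=taxon, type_id=s.type_id)
            for s in segments
        ]
    return cmap, segments
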