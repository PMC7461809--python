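import re

import pytest

from ptdr.core import ModifiedDuplex, load_enzyme_specs


@pytest.fixture(scope="session")
def registry():
    return load_enzyme_specs()


def brute_force_site_starts(seq: str, circular: bool = False) -> set[tuple[str, int]]:
    """Independent oracle: regex scan for GAAC (top) / GTTC (bottom-strand
    GAAC) occurrences, doubling the string for circular wrap-around."""
    text = seq + (seq if circular else "")
    L = len(seq)
    out = set()
    for strand, pat in (("top", "GAAC"), ("bottom", "GTTC")):
        for m in re.finditer(f"(?=({pat}))", text):
            s = m.start()
            if s < L and (circular or s + 4 <= L):
                out.add((strand, s % L))
    return out


def make_duplex(seq: str, topology: str = "linear", dup_id: str = "d") -> ModifiedDuplex:
    return ModifiedDuplex(id=dup_id, top_seq=seq, topology=topology)
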