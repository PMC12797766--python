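"""Packaged toy inputs generated on the fly (no data files shipped)."""

from __future__ import annotations

import numpy as np

#: example well barcode from the reference TSO design
EXAMPLE_BARCODE = "AAAGTAGTCAAGCCTA"

#: the corresponding full TSO sequence (riboguanines as DNA G)
EXAMPLE_TSO = "CTACACGACGCTCTTCCGATCTAAAGTAGTCAAGCCTANNNNNNNNNTTTCTTATATGGG"


def toy_whitelist(n: int = 2000, seed: int = 0, barcode_len: int = 16) -> list[str]:
    """Deterministic stand-in for a vendor barcode whitelist.

    Random 16-mers with the example barcode placed first, so greedy
    selection always anchors on it.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seen = {EXAMPLE_BARCODE}
    out = [EXAMPLE_BARCODE]
    while len(out) < n:
        bc = rng.choice(bases, size=barcode_len).tobytes().decode()
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out
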