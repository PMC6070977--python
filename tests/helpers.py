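"""Shared independent oracles for the test suite."""

import numpy as np


def naive_occurrences(references: dict[str, str], query: str):
    """Independent both-strand exact-occurrence oracle (str.find scan)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = query.translate(comp)[::-1]
    out = []
    for name in references:
        seq = references[name]
        for q, strand in ((query, "+"), (rc, "-")):
            start = seq.find(q)
            while start != -1:
                out.append((name, start, strand))
                start = seq.find(q, start + 1)
    return sorted(out)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
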