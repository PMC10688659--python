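"""Independent brute-force decision table for the group classification rules.

Written against the rule statements directly, using integer arithmetic for
the 50% threshold (m meets the cutoff iff 2*m >= size), deliberately not
sharing code with the package implementation.
"""


def classify_oracle(size: int, e: int, b: int, n: int) -> tuple[str, int]:
    """Return (classification, score) for one cell at the default policy."""
    mentions = e + b + n
    if 2 * mentions < size:
        return "excluded", 0
    if 2 * n >= size:
        return "neutral", 0
    if e == b:
        return "neutral", 0
    if size % 2 == 1 and e >= 1 and b >= 1 and abs(e - b) <= 1:
        return "neutral", 0
    if 2 * b >= size:
        return "barrier", -b
    if 2 * e >= size:
        return "enabler", e
    return "indeterminate", 0


def all_cells(max_size: int):
    """Every (size, e, b, n) with e + b + n <= size, size in 1..max_size."""
    for size in range(1, max_size + 1):
        for e in range(size + 1):
            for b in range(size + 1 - e):
                for n in range(size + 1 - e - b):
                    yield size, e, b, n
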