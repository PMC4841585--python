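"""The residue alphabet shared by all modules.

Windows are written over 21 letters: the 20 standard amino acids in
alphabetical one-letter order, plus the dummy residue ``X`` used to pad
windows that run past a protein terminus.  ``X`` is always the last index,
matching the convention that 'A' maps to the first one-hot slot and 'X' to
the last.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
PAD: str = "X"
ALPHABET: str = AMINO_ACIDS + PAD

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

# Ambiguity/rare codes tolerated in real-world FASTA, mapped to the dummy
# residue rather than rejected: B (D/N), Z (E/Q), J (I/L), U (selenocysteine),
# O (pyrrolysine), and the stop marker '*'.
NONSTANDARD: dict[str, str] = {c: PAD for c in "BZJUO*"}


def sanitize(sequence: str) -> tuple[str, list[str]]:
    """Uppercase a raw sequence and map non-standard residue codes to 'X'.

    Returns the cleaned sequence and the sorted list of distinct
    non-standard characters that were replaced (empty if none).
    Characters outside the amino-acid alphabet and the tolerated ambiguity
    codes raise ``ValueError``.
    """
    seq = sequence.upper()
    replaced: set[str] = set()
    out = []
    for ch in seq:
        if ch in AA_INDEX:
            out.append(ch)
        elif ch in NONSTANDARD:
            replaced.add(ch)
            out.append(NONSTANDARD[ch])
        else:
            raise ValueError(f"invalid residue character {ch!r} in sequence")
    return "".join(out), sorted(replaced)
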