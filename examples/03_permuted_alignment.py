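"""Rendering a circularly permuted alignment with key-residue annotations.

The query's helices are expressed out of canonical order (D-H first, then
the IQ motif, then A-C, as in androglobin); the renderer prints each helix
block in canonical order with the query placed at its consensus offset,
marks the chain break with '/', and flags key residues on a marker line
('a' = CD1 aromatic, '#' = disulfide cysteine).
"""

from helixvote import (
    Annotation,
    OffsetRange,
    PermutedLayout,
    SyntheticSpec,
    assemble_permuted_alignment,
    consensus,
    default_windows,
    generate_family,
    permuted_alignment_fasta,
    plant_offsets,
    random_seed_sequence,
    tally,
)

ancestor = random_seed_sequence(140, rng_seed=5)
template = generate_family(
    SyntheticSpec(seed_sequence=ancestor, n_sequences=10, target_identity=0.45,
                  rng_seed=1, family_id="globin"),
    windows=default_windows("globin"),
)
query = generate_family(
    SyntheticSpec(seed_sequence=ancestor, n_sequences=10, target_identity=0.45,
                  rng_seed=2, family_id="permuted"),
    windows=default_windows("permuted"),
)
# displace helices B and G by +2 and -1; the votes will find both
query = plant_offsets(query, {"B": 2, "G": -1}, rng_seed=3)

results = {
    helix: consensus([tally(template, query, helix, OffsetRange(-6, 6))])
    for helix in ("A", "B", "E", "F", "G", "H")
}

layout = PermutedLayout(
    query_order=("E", "F", "G", "H", "IQ", "A", "B", "C", "D"),
    chain_break_after="H",
    annotations={
        "CD1": Annotation("CD1", "globin", 10, "a"),
        "SS": Annotation("SS", "permuted", 30, "#"),
    },
)

text = assemble_permuted_alignment([template], query, results, layout)
print(text)
print("Each block shows the template window, the query window read at its "
      "winning offset (flanks lowercase), '/' at the query chain break, and "
      "annotation glyphs under their residues.")
print("\nAligned FASTA of the same layout:\n")
print(permuted_alignment_fasta([template], query, results, layout))
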