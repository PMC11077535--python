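"""Offset voting on one helix: recovering a planted +4 shift.

Two families of remote homologues are generated from a common ancestral
sequence at ~30% pairwise identity, and the query family's helix E content
is displaced four residues to the right.  Every cross-family sequence pair
then votes for its best-scoring offset; the vote profile should peak at +4.
"""

from helixvote import (
    OffsetRange,
    SyntheticSpec,
    default_windows,
    generate_family,
    plant_offset,
    random_seed_sequence,
    tally,
)

ancestor = random_seed_sequence(140, rng_seed=42)
template = generate_family(
    SyntheticSpec(seed_sequence=ancestor, n_sequences=15, target_identity=0.3,
                  rng_seed=1, family_id="template"),
    windows=default_windows("template"),
)
query = generate_family(
    SyntheticSpec(seed_sequence=ancestor, n_sequences=15, target_identity=0.3,
                  rng_seed=2, family_id="query"),
    windows=default_windows("query"),
)
query = plant_offset(query, "E", 4, rng_seed=3)

table = tally(template, query, "E", OffsetRange(-10, 10))

print(f"pairs voting: {table.n_pairs}")
print("offset  mean votes  scaled")
for offset, mean, norm in zip(table.offsets, table.mean_votes, table.normalized):
    bar = "#" * int(40 * norm)
    print(f"{offset:+3d}    {mean:8.1f}   {norm:5.3f} {bar}")
print(f"\nwinning offset: {table.winning_offset:+d} "
      f"(mean {table.displayed_mean(table.winning_offset)} votes)")
print("A positive offset means the query helix sits that many residues to "
      "the right of the template's helix window; the peak at +4 recovers "
      "the planted displacement despite twilight-zone identity.")
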