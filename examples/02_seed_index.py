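"""Index three MSAs by k-mer seeds and inspect the ranking of one seed.

Three MSAs of 10, 7 and 3 rows contain the seed MEP 2, 4 and 3 times. The
index ranks MSAs per seed by the occurrence count normalized by row count,
so the small MSA where every row carries the seed outranks the large MSA
where it is rare; a per-seed cutoff then keeps only the top entries.
"""

from proteograph import Msa, SeedParams, build_index, normalized_counts

filler = "WGHKLNQRV"


def msa(msa_id: str, n_rows: int, n_with_seed: int) -> Msa:
    rows = [
        ("MEP" + filler) if i < n_with_seed else ("AAA" + filler)
        for i in range(n_rows)
    ]
    return Msa(msa_id, [f"r{i}" for i in range(n_rows)], rows)


msas = [msa("m1", 10, 2), msa("m2", 7, 4), msa("m3", 3, 3)]
params = SeedParams(k=3)

counts = normalized_counts(msas, params)["MEP"]
print("normalized counts for seed MEP (occurrences / rows):")
for mid in ("m1", "m2", "m3"):
    print(f"  {mid}: {counts[mid]:.2f}")

for limit in (2, 0):
    idx = build_index(msas, params, seed_limit=limit)
    label = f"cutoff {limit}" if limit else "unlimited"
    print(f"index entry for MEP ({label}): {idx.entries['MEP']}")
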