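"""Build the three train/test task splits on synthetic data.

Positional splits (genome-half and odd/even chromosome) partition reads of
species the model will see in training; the cross-species split holds out
whole species, graded into four difficulty bins by the Jensen-Shannon
divergence of k-mer composition between each test genome and the training
pool.
"""

import numpy as np

import porebench as pb

# genome-half rule
maps = [pb.ReadMapping(f"r{i}", "genome", s, s + 120)
        for i, s in enumerate(range(0, 880, 40))]
half = pb.split_reads_positional(maps, {"genome": 1000}, mode="genome_half")
print(f"genome-half:  {len(half.train_read_ids)} train, "
      f"{len(half.test_read_ids)} test, {len(half.discarded_read_ids)} discarded "
      "(midpoint-spanning reads)")

# odd/even chromosome rule
chrom_maps = [pb.ReadMapping(f"c{i}", f"chr{c}", 0, 100)
              for i, c in enumerate(["1", "2", "3", "4", "X"])]
oe = pb.split_reads_positional(chrom_maps, mode="odd_even_chromosome")
print(f"odd/even:     {len(oe.train_read_ids)} train, {len(oe.test_read_ids)} test, "
      f"{len(oe.discarded_read_ids)} discarded (non-numeric chromosome)")

# cross-species split: 12 genomes in 3 composition clusters
rng = np.random.default_rng(5)
genomes = {
    f"sp{i:02d}": [pb.generate_reference(
        30_000, gc_fraction=[0.3, 0.5, 0.7][i % 3], seed=int(rng.integers(2**31))
    ).sequence]
    for i in range(12)
}
matrix = pb.species_distance_matrix(genomes, k=5)
split = pb.select_train_species(matrix, genomes, min_train=10, max_train=12, seed=9)
train = sorted(sp for sp, r in split.species_roles.items() if r == "train")
print(f"cross-species: {len(train)} training species; test difficulty bins: "
      f"{split.difficulty_bins}")
print()
print("Each test species' bin (1 = close to the training pool, 4 = far)")
print("comes from its 5-mer-composition distance to the nearest trainer.")
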