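"""Curating a raw bioactivity table into a CPI network.

Builds a small raw table in memory (mixed species, weak affinities, a
duplicate measurement), applies the curation criteria - human only,
affinity < 10 uM, valid sequence >= 100 residues, organic compound with
molecular weight 100-600 Da, proteins with >= 3 active compounds - and
prints the per-criterion removal counts and the resulting network summary.
"""

from cpinet import InteractionRecord, apply_curation_filters, build_network, network_stats

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 4  # 132 residues
sequences = {"ADRB2": SEQ, "DRD2": SEQ, "HTR2A": SEQ[:50]}  # HTR2A too short

records = []
for i, chem in enumerate(["C01", "C02", "C03", "C04"]):
    records.append(InteractionRecord(chem, "ADRB2", "Ki", 0.05 * (i + 1),
                                     smiles="CCN(CC)CCOc1ccccc1", species="human"))
records += [
    InteractionRecord("C01", "ADRB2", "Ki", 0.5, species="human"),   # duplicate pair
    InteractionRecord("C05", "ADRB2", "Ki", 25.0, species="human"),  # too weak
    InteractionRecord("C06", "ADRB2", "Ki", 0.1, species="rat"),     # wrong species
    InteractionRecord("C07", "HTR2A", "Ki", 0.1, species="human"),   # bad sequence
    InteractionRecord("C01", "DRD2", "Ki", 1.0, species="human"),    # DRD2 under-connected
]

retained, report = apply_curation_filters(records, sequences)
print("curation report:")
for key, count in report.as_dict().items():
    print(f"  {key}: {count}")

net = build_network(retained)
stats = network_stats(net)
print(f"\nnetwork: {stats.n_chemicals} chemicals x {stats.n_proteins} proteins, "
      f"{stats.n_interactions} interactions")
print(f"mean chemical degree {stats.mean_chemical_degree:.2f}, "
      f"mean protein degree {stats.mean_protein_degree:.1f}, "
      f"sparsity {stats.sparsity_percent:.2f}%")
print("  -> sparsity is the fraction of all possible chemical-protein pairs "
      "that are observed links")
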