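"""Harmonize a simulated patient-derived xenograft (PDX) matrix.

A PDX expression matrix mixes human (graft) and mouse (host) transcripts.
This example simulates such a mixture with CellRanger-style genome
prefixes, detects each feature's species, converts only the mouse portion
to human orthologs and merges it with the native human counts.
"""

from orthomapper import (
    ConversionPolicy,
    SimulationDesign,
    TableDesign,
    convert_pdx,
    detect_species,
    simulate_pdx,
)

X, truth, table = simulate_pdx(
    human_design=SimulationDesign(n_genes=60, n_cells=40, n_groups=2, seed=1),
    mouse_design=SimulationDesign(n_genes=80, n_cells=40, n_groups=2, seed=2),
    table_design=TableDesign(
        n_one2one=50, n_one2many=6, n_many2many_blocks=2, block_size=3,
        n_unmapped=18, seed=3,
    ),
    prefix_mode=True,  # features look like GRCh38_TP53 / mm10_Trp53
)

partition = detect_species(X, table, human_prefix="GRCh38_", nonhuman_prefix="mm10_")
print(f"detection method: {partition.method}")
print(f"human features:    {len(partition.human_features)}")
print(f"mouse features:    {len(partition.nonhuman_features)}")
print(f"ambiguous:         {len(partition.ambiguous_features)}")

result = convert_pdx(
    X, table, ConversionPolicy(), human_prefix="GRCh38_", nonhuman_prefix="mm10_"
)

extras = result.report.extras
print()
print(f"human input counts:            {extras['pdx_human_input_total']}")
print(f"mouse input counts:            {extras['pdx_nonhuman_input_total']}")
print(f"mouse counts after conversion: {extras['pdx_converted_nonhuman_total']}")
print(f"harmonized ('{result.name}') total:  {extras['pdx_merged_total']}")
print(f"harmonized features:           {result.converted.n_features}")

# The harmonized total always equals human + converted-mouse exactly: the
# merge never invents or loses counts. Mouse counts can shrink (unmapped host
# genes dropped) or grow (one2many expansion) during conversion, and rows
# whose converted symbol collides with a native human gene are summed.
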