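"""Synthetic small-molecule library grouped by scaffold class.

A hand-assembled list of simple, valid SMILES used by the synthetic-data
generator's SMILES mode. The six classes are loose scaffold groups (aliphatic
alcohols/ethers, benzene derivatives, carboxylic acids/esters, amines/amides,
N/O/S heterocycles, carbocycles/polyols) so that within-class Tanimoto
similarity exceeds between-class similarity on average. This is a synthetic
stand-in for a screened chemical library, not curated assay data.
"""

SMILES_CLASSES: dict[str, list[str]] = {
    "alcohol_ether": [
        "CCO", "CCCO", "CCCCO", "CC(C)O", "CCC(C)O", "CCOCC", "COC",
        "CCCCCO", "CC(C)(C)O", "OCCO", "OCCCO", "OCC(O)CO", "CCOC(C)C",
        "CCCCCCO", "CC(O)CO", "CCC(O)CC",
    ],
    "benzene": [
        "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "COc1ccccc1",
        "Nc1ccccc1", "Clc1ccccc1", "Cc1ccc(C)cc1", "Cc1ccc(O)cc1",
        "Oc1ccc(Cl)cc1", "COc1ccc(C)cc1", "Cc1cccc(C)c1", "Nc1ccc(C)cc1",
        "Clc1ccc(Cl)cc1", "OCc1ccccc1", "CCOc1ccccc1",
    ],
    "acid_ester": [
        "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CC(=O)OC", "CC(=O)OCC",
        "CCOC(=O)CC", "OC(=O)CC(=O)O", "OC(=O)CCC(=O)O", "CC(O)C(=O)O",
        "OC(=O)c1ccccc1", "CC(=O)Oc1ccccc1", "COC(=O)c1ccccc1",
        "CC(C)C(=O)O", "OC(=O)CO", "CCCCC(=O)O", "CCCCOC(C)=O",
    ],
    "amine_amide": [
        "CCN", "CCCN", "CCNCC", "CN(C)C", "CC(=O)N", "CC(=O)NC",
        "CCC(=O)N", "NCCO", "NCCCO", "NCCN", "CNC(=O)C", "CC(N)C(=O)O",
        "NCC(=O)O", "CC(C)(N)C", "NCCc1ccccc1", "CNCC(=O)O",
    ],
    "heterocycle": [
        "c1ccncc1", "Cc1ccncc1", "CCc1ccncc1", "Oc1ccncc1", "Nc1ccncc1",
        "c1ccoc1", "Cc1ccco1", "c1ccsc1", "Cc1cccs1", "c1cc[nH]c1",
        "Cc1ccc[nH]1", "c1cnccn1", "c1ccnnc1", "Cc1cnccn1", "Cc1cccnc1",
        "CCc1cccnc1",
    ],
    "carbocycle_polyol": [
        "C1CCCCC1", "C1CCCC1", "OC1CCCCC1", "OC1CCCC1", "C1CCOC1",
        "C1CCOCC1", "O=C1CCCCC1", "O=C1CCCC1", "CC1CCCCC1",
        "OC1CCC(O)CC1", "C1CCNCC1", "CC1CCCO1", "O=C1OCCC1",
        "OCC1OC(O)C(O)C(O)C1O", "OCC(O)C(O)CO", "OCC(O)CO",
    ],
}
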