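import pytest

from racemkit import GroupContributionTable

# One representative structure per stereogenic center type A-N.  The M row
# needs two *different* aryl groups that both classify as "phenyl", otherwise
# the carbon is not stereogenic; a 4-chlorophenyl serves.
CENTER_TYPE_FIXTURES = {
    "A": "CC(=O)NC(c1ccccc1)C(=O)OC",  # N-acetyl phenylglycine methyl ester
    "B": "CC(=O)NC(c1ccccc1)C(N)=O",
    "C": "CC(=O)NC(c1ccco1)C(=O)OC",
    "D": "CC1NC(=O)NC1=O",  # 5-methylhydantoin
    "E": "O=C1NC(=O)C(c2ccccc2)N1",  # 5-phenylhydantoin
    "F": "CC1NC(=S)NC1=O",  # 5-methyl-2-thiohydantoin
    "G": "CC(NC(C)=S)C(=O)NC",
    "H": "CC(C(C)=O)N(C)C",
    "I": "CC(N)C(C)=O",
    "J": "CC(c1ccco1)C(=O)O",
    "K": "CSC(C)C(=O)NC",
    "L": "CC(N1C(=O)CCC1=O)C(=O)NC",
    "M": "Clc1ccc(cc1)C(c1ccccc1)c1ccco1",
    "N": "COC(=O)C(c1ccccc1)N(C)C",  # clopidogrel-like aminoester
}

THALIDOMIDE = "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1"
METHYLHYDANTOIN = "CC1NC(=O)NC1=O"


@pytest.fixture(scope="session")
def builtin_table() -> GroupContributionTable:
    return GroupContributionTable.builtin()
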