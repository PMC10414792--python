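"""Vendored amino-acid index constants.

Fourteen physicochemical/biochemical property scales from the public AAIndex
database (addressed by accession id), transcribed once as static constants so
the package needs no download. Each entry maps the 20 natural residues
(one-letter code) to the property value on the scale's native units.

Property summaries:
  HOPT810101  Hopp-Woods hydrophilicity
  EISD840101  Eisenberg consensus normalized hydrophobicity
  MIYS990104  Miyazawa-Jernigan optimized relative partition energies
  LIFS790101  Lifson-Sander beta-strand conformational preference
  MAXF760101  Maxfield-Scheraga normalized alpha-helix frequency
  CEDJ970104  Cedano composition of intracellular proteins (percent)
  GRAR740102  Grantham polarity
  KYTJ820101  Kyte-Doolittle hydropathy
  MITS020101  Mitaku amphiphilicity index
  DAWD720101  Dawson size parameter
  BIOV880101  Biou information value for accessibility (average fraction 35%)
  CHAM810101  Charton steric parameter
  EISD860101  Eisenberg-McLachlan atomic solvation free energy
  BIGC670101  Bigelow residue volume
"""

# Residue order within each dict is alphabetical one-letter code; the
# encoders module re-indexes through its own frozen alphabet anyway.
AAINDEX_PROPERTIES: dict[str, dict[str, float]] = {
    "HOPT810101": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "EISD840101": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "MIYS990104": {
        "A": -0.04, "C": -0.38, "D": 0.19, "E": 0.23, "F": -0.38,
        "G": 0.09, "H": -0.04, "I": -0.34, "K": 0.33, "L": -0.37,
        "M": -0.30, "N": 0.13, "P": 0.19, "Q": 0.14, "R": 0.07,
        "S": 0.12, "T": 0.03, "V": -0.29, "W": -0.33, "Y": -0.29,
    },
    "LIFS790101": {
        "A": 0.92, "C": 1.16, "D": 0.48, "E": 0.61, "F": 1.25,
        "G": 0.61, "H": 0.93, "I": 1.81, "K": 0.70, "L": 1.30,
        "M": 1.19, "N": 0.60, "P": 0.40, "Q": 0.95, "R": 0.93,
        "S": 0.82, "T": 1.12, "V": 1.81, "W": 1.54, "Y": 1.53,
    },
    "MAXF760101": {
        "A": 1.43, "C": 0.94, "D": 0.92, "E": 1.67, "F": 1.19,
        "G": 0.46, "H": 0.98, "I": 1.04, "K": 1.27, "L": 1.36,
        "M": 1.53, "N": 0.64, "P": 0.49, "Q": 1.22, "R": 1.18,
        "S": 0.70, "T": 0.78, "V": 0.98, "W": 1.01, "Y": 0.69,
    },
    "CEDJ970104": {
        "A": 7.9, "C": 1.9, "D": 5.5, "E": 7.1, "F": 3.9,
        "G": 7.1, "H": 2.1, "I": 5.2, "K": 6.7, "L": 8.6,
        "M": 2.4, "N": 4.0, "P": 5.3, "Q": 4.4, "R": 4.9,
        "S": 6.6, "T": 5.3, "V": 6.8, "W": 1.2, "Y": 3.1,
    },
    "GRAR740102": {
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
        "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
        "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
        "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
    },
    "KYTJ820101": {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
        "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
        "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
        "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    },
    "MITS020101": {
        "A": 0.0, "C": 0.0, "D": 0.0, "E": 1.27, "F": 0.0,
        "G": 0.0, "H": 1.45, "I": 0.0, "K": 3.67, "L": 0.0,
        "M": 0.0, "N": 0.0, "P": 0.0, "Q": 1.25, "R": 2.45,
        "S": 0.0, "T": 0.0, "V": 0.0, "W": 6.93, "Y": 5.06,
    },
    "DAWD720101": {
        "A": 2.5, "C": 3.0, "D": 2.5, "E": 5.0, "F": 6.5,
        "G": 0.5, "H": 6.0, "I": 5.5, "K": 7.0, "L": 5.5,
        "M": 6.0, "N": 5.0, "P": 5.5, "Q": 6.0, "R": 7.5,
        "S": 3.0, "T": 5.0, "V": 5.0, "W": 7.0, "Y": 7.0,
    },
    "BIOV880101": {
        "A": 16.0, "C": 168.0, "D": -78.0, "E": -106.0, "F": 189.0,
        "G": -13.0, "H": 50.0, "I": 151.0, "K": -141.0, "L": 145.0,
        "M": 124.0, "N": -74.0, "P": -20.0, "Q": -73.0, "R": -70.0,
        "S": -70.0, "T": -38.0, "V": 123.0, "W": 145.0, "Y": 53.0,
    },
    "CHAM810101": {
        "A": 0.52, "C": 0.62, "D": 0.76, "E": 0.68, "F": 0.70,
        "G": 0.00, "H": 0.70, "I": 1.02, "K": 0.68, "L": 0.98,
        "M": 0.78, "N": 0.76, "P": 0.36, "Q": 0.68, "R": 0.68,
        "S": 0.53, "T": 0.50, "V": 0.76, "W": 0.70, "Y": 0.70,
    },
    "EISD860101": {
        "A": 0.67, "C": 0.38, "D": -1.2, "E": -0.76, "F": 2.3,
        "G": 0.0, "H": 0.64, "I": 1.9, "K": -0.57, "L": 1.9,
        "M": 2.4, "N": -0.6, "P": 1.2, "Q": -0.22, "R": -2.1,
        "S": 0.01, "T": 0.52, "V": 1.5, "W": 2.6, "Y": 1.6,
    },
    "BIGC670101": {
        "A": 52.6, "C": 68.3, "D": 68.4, "E": 84.7, "F": 113.9,
        "G": 36.3, "H": 91.9, "I": 102.0, "K": 105.1, "L": 102.0,
        "M": 97.7, "N": 75.7, "P": 73.6, "Q": 89.7, "R": 109.1,
        "S": 54.9, "T": 71.2, "V": 85.1, "W": 135.4, "Y": 116.2,
    },
}

#: Accession order used for the 14 columns of the AAIndex encoding.
AAINDEX_ACCESSIONS: tuple[str, ...] = tuple(AAINDEX_PROPERTIES)
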