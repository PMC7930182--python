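"""Regenerate the packaged PAM10 substitution matrix.

The 10-PAM log-odds matrix is derived by the Dayhoff chain from the
high-precision 250-PAM relatedness-odds matrix (MDM78, Dayhoff/Schwartz 1978
"Matrices for Detecting Distant Relationships", shipped with Biopython):

  1. odds -> mutation-probability matrix M250[i,j] = f_j * 10**S250[i,j],
     columns renormalised to sum to one (absorbs the 0.01 rounding of MDM78);
  2. per-PAM rate matrix Q = logm(M250) / 250;
  3. M10 = expm(10 * Q);
  4. symmetrised odds o_ij = sqrt((M10_ij * f_j) * (M10_ji * f_i)) / (f_i * f_j);
  5. scores = round(10 * log10(o)), the conventional Dayhoff scale.

The amino-acid frequencies f are the Dayhoff 1978 composition. Output is a
Biopython-readable substitution-matrix text file; the package loads the frozen
copy at src/cx3score/data/pam10.txt and asserts its checksum, so this script
only needs rerunning if the construction itself changes.
"""

import hashlib
import sys
from pathlib import Path

import numpy as np
from scipy.linalg import expm, logm
from Bio.Align import substitution_matrices

AAS = "ARNDCQEGHILKMFPSTWYV"
DAYHOFF_FREQS = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


def build_pam10() -> np.ndarray:
    mdm = substitution_matrices.load("MDM78")
    s250 = np.array([[mdm[a, b] for b in AAS] for a in AAS])
    f = np.array([DAYHOFF_FREQS[a] for a in AAS])
    f = f / f.sum()
    m250 = (10.0 ** s250) * f[None, :]
    m250 /= m250.sum(axis=0, keepdims=True)
    q = np.real(logm(m250)) / 250.0
    m10 = expm(10.0 * q)
    joint = m10 * f[None, :]
    odds = np.sqrt(joint * joint.T) / (f[:, None] * f[None, :])
    return np.round(10.0 * np.log10(odds)).astype(int)


def write_matrix(scores: np.ndarray, path: Path) -> str:
    lines = ["# PAM10 log-odds (10*log10), Dayhoff chain from MDM78; see scripts/make_pam10.py"]
    lines.append("   " + "  ".join(f"{a:>3s}" for a in AAS))
    for i, a in enumerate(AAS):
        lines.append(a + " " + " ".join(f"{scores[i, j]:4d}" for j in range(20)))
    text = "\n".join(lines) + "\n"
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


if __name__ == "__main__":
    out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).resolve().parents[1] / "src" / "cx3score" / "data" / "pam10.txt"
    )
    digest = write_matrix(build_pam10(), out)
    print(f"wrote {out}\nsha256 {digest}")
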