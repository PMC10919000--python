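"""Molecular featurization: Morgan fingerprints, physicochemical descriptors, fusion.

Three descriptor spaces are produced from SMILES:

``FGP``
    1024-bit Morgan (circular) fingerprint with radius 8.
``DSC``
    123 two-dimensional physicochemical and topological properties computed
    with RDKit, in the fixed order of a frozen manifest shipped with the
    package (``data/descriptors_123.txt``).
``FUS``
    The concatenation FGP then DSC, length 1147.

All featurizers are scikit-learn transformers operating on sequences of
SMILES strings, so they compose with pipelines and model selection.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Descriptors import MoleculeDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

RDLogger.DisableLog("rdApp.*")

FGP_BITS = 1024
FGP_RADIUS = 8
DSC_LENGTH = 123
FUS_LENGTH = FGP_BITS + DSC_LENGTH

KINDS = ("FGP", "DSC", "FUS")


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"could not parse SMILES: {smiles!r}")
        self.smiles = smiles


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def standardize_smiles(smiles: str) -> str:
    """Return a canonical SMILES, keeping only the largest fragment.

    Salt/solvent components are removed by retaining the fragment with the
    most heavy atoms; stereochemistry is left exactly as given.  The
    operation is idempotent.
    """
    mol = _mol(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def load_descriptor_schema() -> list[str]:
    """The frozen, ordered list of the 123 descriptor names."""
    text = resources.files("targetfish.data").joinpath("descriptors_123.txt").read_text()
    names = [line.strip() for line in text.splitlines() if line.strip()]
    if len(names) != DSC_LENGTH:
        raise RuntimeError(
            f"descriptor manifest must list exactly {DSC_LENGTH} names, found {len(names)}"
        )
    if len(set(names)) != len(names):
        raise RuntimeError("descriptor manifest contains duplicate names")
    return names


class DescriptorSchema:
    """Featurization configuration: fingerprint geometry plus the property manifest."""

    def __init__(self, radius: int = FGP_RADIUS, n_bits: int = FGP_BITS):
        self.radius = radius
        self.n_bits = n_bits
        self.property_names = load_descriptor_schema()

    def sidecar(self) -> dict:
        """JSON-serializable record of the schema for persisted feature matrices."""
        import rdkit

        return {
            "radius": self.radius,
            "n_bits": self.n_bits,
            "n_properties": len(self.property_names),
            "property_names": self.property_names,
            "rdkit_version": rdkit.__version__,
        }


class MorganFingerprinter(BaseEstimator, TransformerMixin):
    """Transform SMILES into binary Morgan fingerprints (the FGP space).

    Parameters
    ----------
    radius : int, default=8
        Maximum radius of the circular atom environments.
    n_bits : int, default=1024
        Length of the folded bit vector.
    """

    kind = "FGP"

    def __init__(self, radius: int = FGP_RADIUS, n_bits: int = FGP_BITS):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X, y=None):
        self.n_features_out_ = self.n_bits
        return self

    def transform(self, X) -> np.ndarray:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        out = np.zeros((len(X), self.n_bits), dtype=np.float64)
        for i, smi in enumerate(X):
            fp = gen.GetFingerprint(_mol(smi))
            out[i, list(fp.GetOnBits())] = 1.0
        return out


class PropertyCalculator(BaseEstimator, TransformerMixin):
    """Transform SMILES into the 123 physicochemical properties (the DSC space)."""

    kind = "DSC"

    def fit(self, X, y=None):
        self.property_names_ = load_descriptor_schema()
        self.n_features_out_ = len(self.property_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "property_names_"):
            self.fit(X)
        calc = MoleculeDescriptors.MolecularDescriptorCalculator(self.property_names_)
        out = np.empty((len(X), len(self.property_names_)), dtype=np.float64)
        for i, smi in enumerate(X):
            vals = np.asarray(calc.CalcDescriptors(_mol(smi)), dtype=np.float64)
            if not np.all(np.isfinite(vals)):
                bad = [n for n, v in zip(self.property_names_, vals) if not np.isfinite(v)]
                raise ValueError(
                    f"descriptor(s) {bad} evaluated non-finite on SMILES {smi!r}"
                )
            out[i] = vals
        return out


class FusedFeaturizer(BaseEstimator, TransformerMixin):
    """Concatenate the FGP and DSC blocks into the FUS space (length 1147)."""

    kind = "FUS"

    def __init__(self, radius: int = FGP_RADIUS, n_bits: int = FGP_BITS):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X, y=None):
        self._fgp = MorganFingerprinter(self.radius, self.n_bits).fit(X)
        self._dsc = PropertyCalculator().fit(X)
        self.n_features_out_ = self._fgp.n_features_out_ + self._dsc.n_features_out_
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "_fgp"):
            self.fit(X)
        return fuse(self._fgp.transform(X), self._dsc.transform(X))


def fingerprint(smiles: str, schema: DescriptorSchema | None = None) -> np.ndarray:
    """Morgan fingerprint of one molecule as a binary vector."""
    schema = schema or DescriptorSchema()
    return MorganFingerprinter(schema.radius, schema.n_bits).fit([]).transform([smiles])[0]


def properties(smiles: str, schema: DescriptorSchema | None = None) -> np.ndarray:
    """The 123-property descriptor vector of one molecule."""
    return PropertyCalculator().fit([]).transform([smiles])[0]


def fuse(fgp: np.ndarray, dsc: np.ndarray) -> np.ndarray:
    """Concatenate FGP and DSC blocks (FGP first)."""
    single = np.ndim(fgp) == 1 and np.ndim(dsc) == 1
    fgp = np.atleast_2d(np.asarray(fgp, dtype=float))
    dsc = np.atleast_2d(np.asarray(dsc, dtype=float))
    if fgp.shape[0] != dsc.shape[0]:
        raise ValueError("FGP and DSC blocks must describe the same molecules")
    if not np.isin(fgp, (0.0, 1.0)).all():
        raise ValueError("first argument must be a binary FGP block")
    out = np.hstack([fgp, dsc])
    return out[0] if single else out


def featurizer_for(kind: str, schema: DescriptorSchema | None = None):
    """Return the transformer producing the requested descriptor space."""
    schema = schema or DescriptorSchema()
    if kind == "FGP":
        return MorganFingerprinter(schema.radius, schema.n_bits)
    if kind == "DSC":
        return PropertyCalculator()
    if kind == "FUS":
        return FusedFeaturizer(schema.radius, schema.n_bits)
    raise ValueError(f"unknown descriptor kind {kind!r}; expected one of {KINDS}")


def featurize_smiles(smiles_list, kind: str, schema: DescriptorSchema | None = None) -> np.ndarray:
    """Feature matrix (n_molecules x d) for a list of SMILES in one descriptor space."""
    return featurizer_for(kind, schema).fit(smiles_list).transform(smiles_list)


def write_features(X: np.ndarray, ids, kind: str, out_csv, sidecar_json=None) -> None:
    """Persist a feature matrix as CSV with a JSON sidecar describing the schema."""
    import pandas as pd

    df = pd.DataFrame(X)
    df.insert(0, "compound_id", list(ids))
    df.to_csv(out_csv, index=False)
    if sidecar_json is not None:
        meta = DescriptorSchema().sidecar()
        meta["kind"] = kind
        with open(sidecar_json, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated ID."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{i}"
            out.append((cid, smi))
    return out
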