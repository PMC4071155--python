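"""Reading and writing coded genotype data and fitted classifiers.

TSV layout: a header row ``sample_id<TAB>class<TAB><snp ids...>`` followed
by one row per sample with integer genotype codes 0/1/2.  Missing values
are rejected.  An optional VCF reader codes biallelic SNP records by
in-sample minor allele count; multiallelic or missing-genotype records are
skipped (counts are logged).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .classifiers import BayesSNPClassifier, LinearSNPClassifier
from .design import GenotypeMatrix

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
    "classifier_to_json",
    "classifier_from_json",
]

logger = logging.getLogger(__name__)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "class"]:
        raise ValueError(
            "expected header 'sample_id<TAB>class<TAB><snp ids...>', "
            f"got columns {list(df.columns[:2])}"
        )
    snp_ids = list(df.columns[2:])
    if not snp_ids:
        raise ValueError("no SNP columns found")
    geno = df[snp_ids]
    if geno.isna().any().any():
        bad = geno.isna().any()
        raise ValueError(
            f"missing genotypes are not allowed (first NA column: "
            f"{bad.index[bad][0]!r})"
        )
    values = geno.to_numpy()
    if not np.isin(values, (0, 1, 2)).all():
        raise ValueError("genotype cells must be integers 0/1/2")
    return GenotypeMatrix(
        values=values.astype(np.int8),
        labels=df["class"].to_numpy(),
        snp_ids=snp_ids,
    )


def write_genotype_tsv(data: GenotypeMatrix, path, sample_ids=None) -> None:
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(data.n_samples)]
    df = pd.DataFrame(data.values, columns=data.snp_ids)
    df.insert(0, "class", data.labels)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path, labels=None) -> GenotypeMatrix:
    """Code biallelic SNPs from a VCF by in-sample minor allele count.

    For each biallelic record the ALT-allele dosage per sample is computed;
    if the ALT allele is the in-sample major allele the coding is flipped so
    the code counts the minor allele.  Records that are multiallelic or
    contain missing genotypes are skipped and counted.  ``labels`` assigns
    a class per sample (defaults to 1 for all; the TSV format is the
    primary labelled interface).
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = vcf.samples
    columns, ids = [], []
    n_multi = n_missing = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_multi += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        if (gts < 0).any():
            n_missing += 1
            continue
        dosage = gts.sum(axis=1)
        if dosage.mean() > 1.0:  # ALT is the major allele here: flip
            dosage = 2 - dosage
        columns.append(dosage)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if n_multi or n_missing:
        logger.info(
            "skipped %d multiallelic/non-SNP and %d missing-genotype records",
            n_multi,
            n_missing,
        )
    if not columns:
        raise ValueError("no usable biallelic SNP records in VCF")
    values = np.column_stack(columns).astype(np.int8)
    if labels is None:
        labels = np.ones(len(samples), dtype=int)
    return GenotypeMatrix(values=values, labels=np.asarray(labels), snp_ids=ids)


def classifier_to_json(clf) -> str:
    """Serialize a fitted classifier to a JSON document."""
    if isinstance(clf, LinearSNPClassifier):
        doc = {
            "kind": "linear",
            "alpha": clf.alpha,
            "theta_hat": clf.theta_hat_.tolist(),
            "priors": clf.priors_.tolist(),
            "weights": clf.weights_.astype(int).tolist(),
            "n_per_class": clf.n_per_class_.tolist(),
            "classes": clf.classes_.tolist(),
        }
    elif isinstance(clf, BayesSNPClassifier):
        doc = {
            "kind": "bayes",
            "theta": clf.profile_.theta.tolist(),
            "priors": clf.profile_.priors.tolist(),
            "l": clf.l_,
        }
    else:
        raise TypeError(f"cannot serialize {type(clf).__name__}")
    return json.dumps(doc)


def classifier_from_json(doc: str):
    """Rebuild a fitted classifier from :func:`classifier_to_json` output."""
    data = json.loads(doc)
    if data["kind"] == "bayes":
        return BayesSNPClassifier(
            theta=np.array(data["theta"]), priors=np.array(data["priors"]),
            l=data["l"],
        ).fit()
    if data["kind"] == "linear":
        clf = LinearSNPClassifier(alpha=data["alpha"], priors=np.array(data["priors"]))
        theta = np.array(data["theta_hat"])
        from .classifiers import pairwise_coefficients

        clf.classes_ = np.array(data["classes"])
        clf.theta_hat_ = theta
        clf.n_per_class_ = np.array(data["n_per_class"])
        clf.priors_ = np.array(data["priors"])
        clf.weights_ = np.array(data["weights"], dtype=bool)
        clf.coef_ = pairwise_coefficients(theta)
        log1m = np.log1p(-theta)
        D = theta.shape[0]
        thresholds = (
            np.log(clf.priors_)[None, :] - np.log(clf.priors_)[:, None]
        )
        for k in range(D):
            for kp in range(D):
                if k != kp:
                    w = clf.weights_[k, kp]
                    thresholds[k, kp] += 2.0 * (log1m[kp, w] - log1m[k, w]).sum()
        clf.thresholds_ = thresholds
        clf.n_features_in_ = theta.shape[1]
        return clf
    raise ValueError(f"unknown classifier kind {data['kind']!r}")
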