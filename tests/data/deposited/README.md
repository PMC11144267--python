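# Deposited coordinate files

The validations in `tests/test_acceptance.py` that compare gate radii and
packing-score correlations against published values read deposited cryo-EM
coordinates from this directory (not redistributed with the package).

Place `<pdbid>.cif` or `<pdbid>.pdb` here, lower-case, e.g.:

    7l2w.cif 7l2p.cif 7mzc.cif 7mzd.cif 7mio.cif 6pvl.cif 7s88.cif 6e2f.cif 7s8c.cif

e.g. `wget https://files.rcsb.org/download/7L2W.cif -O 7l2w.cif`
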