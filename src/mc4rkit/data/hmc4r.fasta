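>hMC4R human melanocortin-4 receptor (332 aa, mature numbering)
MVNSTHRGMHTSLHLWNRSSYRLHSNASESLGKGYSDGGCYEQLFVSPEVFVTLGVISLL
ENILVIVAIAKNKNLHSPMYFFICSLAVADMLVSVSNGSETIVITLLNSTDTDAQSFTVN
IDNVIDSVICSSLLASICSLLSIAVDRYFTIYYALQYHNIMTVKRVGIIISCIWAACTVS
GILFIIYSDSSAVIICLITMFFTMLALMASLYVHMFLMARLHIKRIAVLPGTGAIRQGAN
MKGAITLTILIGVFVVCWAPFFLHLIFYISCPQNPYCVCFMSHFNLYLILIMCNSIIDPL
IYALRSQELRKTFKEIICCYPLGGLCDLSSRY
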