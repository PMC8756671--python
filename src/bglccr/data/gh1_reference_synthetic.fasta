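>GH1_REF_SYN synthetic glucose-tolerant GH1 beta-glucosidase reference (W168/L173); constructed stand-in, not a database sequence
EIGVNDTFLKLGRESLISVGELLLAARDQINLLMLYSGRKMSPHPTSVNGNALVKIQREDRVKVSLSEIIIAYRPYFNGE
LVSATGTRLSAFKGWLGALFAAPEDGKGDMVITNSTFEGSSNGSHDNIITCRNIMIAQNTTGATKAENEAWSLFNLIDCP
FWVPHPKWLGAELSFSPHHDGMKAKFGRSEYSAIVTCPMESDIPSLYDYLDHSLNKKHDMNQELTVWLVAITLPVSYTGA
MIVRAAPAESDGLGDEKKYVNSQFLLYTLTDTGMEYGQLIPYAGEWAGAMGWPQALDEIAVMVMGTSVAQREGRAKHIPI
RLNLRPEDNATRMGRAPQSLGNLVRVELNMIKNCEDDQKAGHGTKLELTRGIVGFVAAIIDAPF
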