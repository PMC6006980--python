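>KS synthetic consensus-like exemplar
AGRNLGMSWSQNPMNYFCKKYWQAGSWMKGFDKQQNQGTACSSGLPEHVYHLMSDLQCGE
HWMDWGASPRNFGRWHGTGTLRKPKMEAGVVWAWNWNKTHSHRSIKSNIGHFWTNKMSFV
ENSGSMLWAC
>AT synthetic consensus-like exemplar
QRRMESENTQFGGPPCTSFSEMYRSGKPAWGMIRNFWTASEYTYRGHSQGYVHQISYFMD
MSHIKKAASGHAFHEYLPNVVRCNRKLNNWEHWTRMMHLHAEPEARCARMLHDIVISSIQ
>DH synthetic consensus-like exemplar
WVLICCKLVVFRVDFSELQIIEASNTTRATYQEHCHRSLGEVLPERGYSYYPWNKMLVAI
QVSATRSRGDGKFPMTCFLRIGHWPMNPMA
>ER synthetic consensus-like exemplar
ICKIDLLLWLMLTSLVVVIIQAYRENMRHADWLMRMDQMRLRHEAVGGVGLSATRWAHDY
SYLCQCKIKHMRMPCQEWPPTIGKDGCQPKHLQHGLHIWP
>KR synthetic consensus-like exemplar
DLHNAVCNKWGGTGSLGEAEMQSAFGISKLCCHFMFMPPDDPYVYKDCHVADYMRAGDYI
VAAVDQWQCCMEFTFNPNPQHGQRESKWKYMKHVNKQGNSSAATNMFGWKGCYLGWLAGL
NLVMAFCMCH
>ACP synthetic consensus-like exemplar
PVHCDCQHRQGAVYTVWWQRWTMTFSVMSKLGIDSINMYCGEQLSTHLQQVKGDNVFGHK
SVVCANTIFE
>TE synthetic consensus-like exemplar
LEYRLEYYIYMRAMVNKNNKQAIGHEDGYYADMNRNMEDKGWSAGDTDFFRSGKSYDRKW
FPDCCCTIFIDKFELICCCERPPCWINWPI
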