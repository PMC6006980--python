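>malAT1 synthetic AT reference, malonyl-CoA specific
QRFMESENTQFGGPPRTSFSQMYRQIDPAWGMIRAFWTASEYTYRGHSQGYVHQISGFMD
MSHIKYAASGHAFHPYLYNVVRCNRKLINHEHWTRMAHQMAEPEARWARMLPDMVVSSIQ
>malAT2 synthetic AT reference, malonyl-CoA specific
QRFMESENTQFGGPPRTSFSEMYRSIDPDWGMIRAFWTASEYTYRGHSQGYVHQIHGFMD
MSHIKYAASGHAFHEYLYNVVRCNRKVINHEHWRRMAHQMAEPEARWARMLPDMVISSIQ
>malAT3 synthetic AT reference, malonyl-CoA specific
QRFMESENTQFGGPPRTSFSHMYRSIDPAWGMIRAFWTASEYTYRGHSQGYVHQIPGFMD
MSHIKYAASGHAFHEYLYNVVRCNRKLINHEHWTRMAHQMHEPEARWARWLPDMVISSIQ
>malAT4 synthetic AT reference, malonyl-CoA specific
QRFMESENTQFGGPPRTSFSEMYRSIDPAWGMIRAFWTASEYTYRGHSQGYVHQISGFMD
MSHIKYAASGHAFHDYLYNVVRCNRKLINHEHWTRMAHQMAEPEARWARMLPDMPIHEIQ
>mmAT1 synthetic AT reference, methylmalonyl-CoA specific
QRDMESANTQFGGPPSTSFSEMYRSAQPAWFMIRDFWTASEYTYRGHSQGYVHQISEFMD
MSHIKCAASGYASHEYLKNVVRCNRKLWNDEHWTRMSHHFAEPEARRARMLVDPVASSIK
>mmAT2 synthetic AT reference, methylmalonyl-CoA specific
QRDMESENTAFGGPPSTSFSEMYRSAQPAWGMIRDFWTASEYTYRGHSQGYMHQISEFMD
MSHITCAASGYASHEYLKNVVRCNRKLWNDEHWTRMSHHFAEPEARRARMLVDPVILSIQ
>mmAT3 synthetic AT reference, methylmalonyl-CoA specific
QRDMESENTQFGGPPSTSFSEMYRSAQPAWGMIRDFWTASEYTYRGHSQGYVHQISEFMD
HSHCKCAASGYASHEYQKNVVRCNRKLWNDEHWTRMSHHFAEPEIRRARMLVDPVISSIQ
>mmAT4 synthetic AT reference, methylmalonyl-CoA specific
QRDMESANTQFGIPPSTSFSEMYRSAQPAWGMIRDFWTASEYTYRGHSQGYVHQISEFMD
MSHIKCAASGYASHEYLKNKVRCNRKLWNDEHWTRISHHFAEPEARRARMLVDPVISSIQ
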