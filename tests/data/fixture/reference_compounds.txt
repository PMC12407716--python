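CRDAMVZIKSXKFV	simulated-genus-records
DSSYKIVIOFKYAU	simulated-genus-records
GLZPCOQZEFWAFX	simulated-genus-records
IYRMWMYZSQPJKC	simulated-genus-records
KZNIFHPLKGYRTM	simulated-genus-records
LNTHITQWFMADLM	simulated-genus-records
ONIBWKKTOPOVIA	simulated-genus-records
OUYCCCASQSFEME	simulated-genus-records
PEDCQBHIVMGVHV	simulated-genus-records
RODXRVNMMDRFIK	simulated-genus-records
RTIXKCRFFJGDFG	simulated-genus-records
RYYVLZVUVIJVGH	simulated-genus-records
SIKJAQJRHWYJAI	simulated-genus-records
SSDMEOFBWCLVEM	simulated-genus-records
WBYWAXJHAXSJNI	simulated-genus-records
WHUUTDBJXJRKMK	simulated-genus-records
ZQPPMHVWECSIRJ	simulated-genus-records
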