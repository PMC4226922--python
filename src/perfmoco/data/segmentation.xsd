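<?xml version="1.0" encoding="UTF-8"?>
<!-- Segmentation workset dialect used by perfmoco. Coordinates are 0-based
     pixel positions, x = column, y = row. The star carries the LV centre in
     its x/y attributes and exactly three ray points on the epicardial
     circumcircle; the first ray point is the RV insertion point. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="workset">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="description" minOccurs="0">
          <xs:complexType>
            <xs:all>
              <xs:element name="RVpeak" type="peakType" minOccurs="0"/>
              <xs:element name="LVpeak" type="peakType" minOccurs="0"/>
            </xs:all>
          </xs:complexType>
        </xs:element>
        <xs:element name="frame" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="star">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="point" type="pointType" minOccurs="3" maxOccurs="3"/>
                  </xs:sequence>
                  <xs:attribute name="x" type="xs:double" use="required"/>
                  <xs:attribute name="y" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="contour" minOccurs="2" maxOccurs="2">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="point" type="pointType" minOccurs="3" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="role" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="endocardium"/>
                        <xs:enumeration value="epicardium"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="image" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="sliceLevel" type="xs:integer"/>
      <xs:attribute name="rvInsertion" type="xs:string"/>
    </xs:complexType>
  </xs:element>
  <xs:complexType name="pointType">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
  </xs:complexType>
  <xs:complexType name="peakType">
    <xs:attribute name="value" type="xs:nonNegativeInteger" use="required"/>
  </xs:complexType>
</xs:schema>
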